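"""Seed-based microRNA target prediction on 3'UTRs.

A miRNA recognises a target mainly through its seed, nucleotides 2-8 from
its 5' end.  Scanning a 3'UTR with an 8-nt window (positions t8..t1 read
5'→3' on the target, t1 opposite miRNA position 1) yields the canonical
site taxonomy:

==========  =========================================================
8mer        t2-t8 pair miRNA 2-8 and t1 is an A
7mer-m8     t2-t8 pair miRNA 2-8, t1 not A
7mer-A1     t2-t7 pair miRNA 2-7, t1 is an A, m8 unpaired
6mer        t2-t7 pair miRNA 2-7 only
off-6mer    t3-t8 pair miRNA 3-8 only
==========  =========================================================

Seed pairing is strict Watson-Crick; when a window satisfies several
definitions the most specific class wins.  Each site also carries the free
energy of the best miRNA:target duplex over the site window extended 30 nt
upstream on the target (where the miRNA 3' half can pair), computed with a
nearest-neighbour stacking model.

Prediction results are filtered the way the study retains interactions:
drop 6mer and off-6mer sites, drop sites weaker than −7 kcal/mol, then
drop any UTR left with fewer than two predicted sites in total, and
aggregate the survivors to one row per (miRNA, gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from bamir._energy_params import (
    ALL_PAIRS,
    DUPLEX_INITIATION,
    STACK_ENERGIES,
    TERMINAL_AU_PENALTY,
    WC_PAIRS,
)
from bamir.io_formats import GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "off-6mer")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class Site:
    """One seed-match occurrence in a 3'UTR."""

    gene_id: str
    mirna_id: str
    utr_position: int  # 0-based start of the 8-nt window
    site_class: str
    energy_kcal_mol: float = 0.0

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.energy_kcal_mol > 0:
            raise ValueError("site energy must be <= 0")


@dataclass(frozen=True)
class EnergyConfig:
    """Parameters of the duplex free-energy model.

    The default evaluates the full miRNA against the site window plus
    ``upstream_extension`` nt of 5'-target context; ``seed_region_only``
    restricts the duplex to the 8-nt site window itself.
    """

    upstream_extension: int = 30
    seed_region_only: bool = False
    allow_wobble: bool = True
    initiation: float = DUPLEX_INITIATION
    terminal_penalty: float = TERMINAL_AU_PENALTY


@dataclass(frozen=True)
class PredictionConfig:
    energy_max: float = -7.0  # retain iff energy <= -7 kcal/mol
    min_sites_per_utr: int = 2
    drop_classes: frozenset[str] = frozenset({"6mer", "off-6mer"})
    # site-count filter scope: per UTR across all miRNAs, or per (miRNA, UTR)
    count_sites_per_pair: bool = False
    energy: EnergyConfig = field(default_factory=EnergyConfig)

    def __post_init__(self) -> None:
        if self.min_sites_per_utr < 1:
            raise ValueError("min_sites_per_utr must be >= 1")


def _wc_match(target_nt: str, mirna_nt: str) -> bool:
    return (target_nt, mirna_nt) in _WC


def classify_seed_site(mirna: SequenceRecord, window: str) -> str | None:
    """Classify an 8-nt target window against a miRNA seed, or return None.

    ``window`` is read 5'→3' on the target, so its last character is t1
    (opposite miRNA position 1) and its first is t8.  Precedence:
    8mer > 7mer-m8 > 7mer-A1 > 6mer > off-6mer.
    """
    if len(window) != 8:
        raise ValueError(f"window must be 8 nt, got {len(window)}")
    m = mirna.sequence
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    # t_i = window[8 - i] for i = 1..8
    t = {i: window[8 - i] for i in range(1, 9)}
    match_2_7 = all(_wc_match(t[i], m[i - 1]) for i in range(2, 8))
    match_2_8 = match_2_7 and _wc_match(t[8], m[7])
    match_3_8 = all(_wc_match(t[i], m[i - 1]) for i in range(3, 9))
    if match_2_8 and t[1] == "A":
        return "8mer"
    if match_2_8:
        return "7mer-m8"
    if match_2_7 and t[1] == "A":
        return "7mer-A1"
    if match_2_7:
        return "6mer"
    if match_3_8:
        return "off-6mer"
    return None


def duplex_energy(
    seq_a: str | SequenceRecord,
    seq_b: str | SequenceRecord,
    config: EnergyConfig | None = None,
) -> float:
    """Free energy (kcal/mol) of the best intermolecular helix between two
    RNA strands, both given 5'→3'.

    The model sums Turner-2004 nearest-neighbour stack energies over the
    best contiguous run of Watson-Crick (and optionally wobble) pairs in
    any antiparallel register, adds the duplex initiation term and a
    penalty for each helix end closed by an A:U or G:U pair, and ignores
    intramolecular structure.  If no pairing arrangement reaches a negative
    total the convention value 0.0 is returned, so the result is never
    positive.  The value is symmetric in the two strands.
    """
    cfg = config or EnergyConfig()
    a = seq_a.sequence if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.sequence if isinstance(seq_b, SequenceRecord) else seq_b
    allowed = ALL_PAIRS if cfg.allow_wobble else WC_PAIRS
    rb = b[::-1]  # antiparallel: a[i] pairs b[j] with j decreasing as i grows
    best = 0.0
    la, lb = len(a), len(rb)
    for shift in range(-(la - 1), lb):
        # diagonal: a[i] vs rb[i + shift]
        i_lo = max(0, -shift)
        i_hi = min(la, lb - shift)
        # scan runs of consecutive allowed pairs along this diagonal
        i = i_lo
        while i < i_hi:
            if (a[i], rb[i + shift]) not in allowed:
                i += 1
                continue
            run_start = i
            while i < i_hi and (a[i], rb[i + shift]) in allowed:
                i += 1
            best = min(best, _best_subhelix(a, rb, shift, run_start, i, cfg))
    return best


def _end_penalty(pair: tuple[str, str], cfg: EnergyConfig) -> float:
    return cfg.terminal_penalty if pair not in (("C", "G"), ("G", "C")) else 0.0


def _best_subhelix(
    a: str, rb: str, shift: int, start: int, stop: int, cfg: EnergyConfig
) -> float:
    """Minimum-energy contiguous sub-helix within a run of pairable positions.

    A helix over pairs p..q costs initiation + the q-p stack terms between
    consecutive pairs + the two end penalties; minimised in one pass over q
    while tracking the best start p.
    """
    # prefix[k] = sum of stack energies for steps start..start+k-1
    best = float("inf")
    prefix = 0.0
    # track max over p <= q of (prefix_at_p - end_penalty(p))
    pair0 = (a[start], rb[start + shift])
    best_start_term = 0.0 - _end_penalty(pair0, cfg)
    for q in range(start, stop):
        if q > start:
            x1, x2 = a[q - 1], a[q]
            y1, y2 = rb[q - 1 + shift], rb[q + shift]
            prefix += STACK_ENERGIES[(x1, x2, y1, y2)]
        pair_q = (a[q], rb[q + shift])
        energy_q = cfg.initiation + prefix + _end_penalty(pair_q, cfg) - best_start_term
        best = min(best, energy_q)
        candidate_start = prefix - _end_penalty(pair_q, cfg)
        best_start_term = max(best_start_term, candidate_start)
    return best


def scan_utr(
    mirna: SequenceRecord,
    utr: SequenceRecord,
    energy_config: EnergyConfig | None = None,
) -> list[Site]:
    """Report every classifiable seed-match site in a 3'UTR (pre-filter).

    All 8-nt windows are tested; overlapping sites are each reported.  Each
    site's energy is the duplex energy of the miRNA against the window
    extended upstream on the target (or the window alone if the model is
    configured seed-region-only).
    """
    cfg = energy_config or EnergyConfig()
    sites: list[Site] = []
    useq = utr.sequence
    for pos in range(len(useq) - 7):
        window = useq[pos : pos + 8]
        site_class = classify_seed_site(mirna, window)
        if site_class is None:
            continue
        if cfg.seed_region_only:
            region = window
        else:
            region = useq[max(0, pos - cfg.upstream_extension) : pos + 8]
        energy = duplex_energy(mirna.sequence, region, cfg)
        sites.append(Site(utr.id, mirna.id, pos, site_class, energy))
    return sites


def predict_targets(
    mirnas: list[SequenceRecord],
    utrs: list[SequenceRecord],
    energy_config: EnergyConfig | None = None,
) -> list[Site]:
    """Scan every miRNA against every UTR; returns the pre-filter site list."""
    sites: list[Site] = []
    for mirna in mirnas:
        for utr in utrs:
            sites.extend(scan_utr(mirna, utr, energy_config))
    return sites


def sites_to_frame(sites: list[Site]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.mirna_id, s.gene_id, s.utr_position, s.site_class, s.energy_kcal_mol) for s in sites],
        columns=["mirna_id", "gene_id", "utr_position", "site_class", "energy_kcal_mol"],
    )


_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}


def filter_interactions(sites: list[Site], config: PredictionConfig | None = None) -> pd.DataFrame:
    """Apply the retention filters and aggregate sites to interactions.

    Sites of a dropped class go first, then sites weaker than the energy
    cutoff (strictly above it; a site exactly at the cutoff is retained),
    then every gene whose total retained site count falls below the
    minimum.  Survivors collapse to one (mirna_id, gene_id) row carrying
    the site count, the most specific site class and the strongest energy.
    """
    cfg = config or PredictionConfig()
    kept = [
        s
        for s in sites
        if s.site_class not in cfg.drop_classes and s.energy_kcal_mol <= cfg.energy_max
    ]
    if cfg.count_sites_per_pair:
        tallies: dict[tuple[str, str], int] = {}
        for s in kept:
            key = (s.mirna_id, s.gene_id)
            tallies[key] = tallies.get(key, 0) + 1
        kept = [s for s in kept if tallies[(s.mirna_id, s.gene_id)] >= cfg.min_sites_per_utr]
    else:
        per_gene: dict[str, int] = {}
        for s in kept:
            per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + 1
        kept = [s for s in kept if per_gene[s.gene_id] >= cfg.min_sites_per_utr]

    rows: dict[tuple[str, str], dict] = {}
    for s in kept:
        key = (s.mirna_id, s.gene_id)
        row = rows.get(key)
        if row is None:
            rows[key] = {
                "mirna_id": s.mirna_id,
                "gene_id": s.gene_id,
                "n_sites": 1,
                "best_class": s.site_class,
                "min_energy": s.energy_kcal_mol,
            }
        else:
            row["n_sites"] += 1
            if _CLASS_RANK[s.site_class] < _CLASS_RANK[row["best_class"]]:
                row["best_class"] = s.site_class
            row["min_energy"] = min(row["min_energy"], s.energy_kcal_mol)
    table = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r["mirna_id"], r["gene_id"])),
        columns=["mirna_id", "gene_id", "n_sites", "best_class", "min_energy"],
    )
    return table


def frame_to_sites(df: pd.DataFrame) -> list[Site]:
    return [
        Site(r.gene_id, r.mirna_id, int(r.utr_position), r.site_class, float(r.energy_kcal_mol))
        for r in df.itertuples()
    ]


UTR_FEATURE_TYPES = ("three_prime_utr", "three_prime_UTR", "3UTR")


def extract_longest_3utrs(
    features: list[tuple[str, str, str, GenomicInterval]],
    genome_sequences: dict[str, str],
) -> list[SequenceRecord]:
    """Per gene, the spliced 3'UTR of the transcript with the longest one.

    ``features`` is the parsed annotation restricted to 3'UTR feature
    types; ``genome_sequences`` maps chromosome name to its full sequence
    (DNA or RNA; normalised here).  Minus-strand UTRs are
    reverse-complemented so every record reads 5'→3'.  Length ties break
    to the lexicographically smallest transcript id.  Record ids are the
    gene ids (one UTR per gene).
    """
    from bamir.io_formats import normalise_rna

    by_transcript: dict[tuple[str, str], list[GenomicInterval]] = {}
    for gene_id, transcript_id, feature, interval in features:
        if feature not in UTR_FEATURE_TYPES:
            continue
        by_transcript.setdefault((gene_id, transcript_id), []).append(interval)

    best: dict[str, tuple[int, str, list[GenomicInterval]]] = {}
    for (gene_id, transcript_id), intervals in by_transcript.items():
        length = sum(len(iv) for iv in intervals)
        current = best.get(gene_id)
        if current is None or (-length, transcript_id) < (-current[0], current[1]):
            best[gene_id] = (length, transcript_id, intervals)

    records = []
    for gene_id in sorted(best):
        length, transcript_id, intervals = best[gene_id]
        intervals = sorted(intervals, key=lambda iv: iv.start)
        chrom = intervals[0].chrom
        if chrom not in genome_sequences:
            logger.warning("gene %s: chromosome %s absent from genome; skipped", gene_id, chrom)
            continue
        genomic = "".join(
            normalise_rna(genome_sequences[chrom][iv.start : iv.end]) for iv in intervals
        )
        if intervals[0].strand == "-":
            genomic = reverse_complement(genomic)
        records.append(SequenceRecord(gene_id, genomic))
    return records
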