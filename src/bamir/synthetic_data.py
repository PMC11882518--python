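"""Seed-controlled synthetic data with ground-truth labels for every stage.

Each generator is a pure function of its spec: the same seed yields
byte-identical output, and truth labels are computed from the spec alone,
never by running the component they are meant to test.

What is emulated, per stage:

* hairpin candidates — a stem-loop (optionally with internal sub-hairpins
  or a recessed/protruding 3' end) plus a collapsed read stack realising
  requested perfect-read counts and 5'-start homogeneity;
* 3'UTRs — background sequence of controlled GC content with seed-match
  sites of chosen class planted at chosen positions, background resampled
  until the planted sites are the only sites;
* count matrices — negative-binomial counts over the 3-domain × 2-stage
  × 2-replicate design with fold changes planted in the posterior domain;
* interactomes — Bernoulli miRNA→gene interaction tables with one miRNA's
  set-gene interactions boosted by a chosen enrichment factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bamir.io_formats import SequenceRecord, StructureRecord, reverse_complement
from bamir.novel_mirna_filter import AlignedRead, HairpinCandidate
from bamir.target_prediction import Site, classify_seed_site

logger = logging.getLogger(__name__)

_NT = np.array(list("ACGU"))
_MAX_BACKGROUND_ATTEMPTS = 100


class SpecError(ValueError):
    """Raised when a simulation spec is invalid or infeasible."""


# ---------------------------------------------------------------------------
# hairpin candidates


@dataclass(frozen=True)
class HairpinSimSpec:
    stem_length: int = 22
    loop_length: int = 8
    mature_reads_0mm: int = 40
    star_reads_0mm: int = 15
    homogeneity_target: float = 0.9
    overhang_3p: int = 2
    n_subhairpins: int = 1
    mfe_per_nt_target: float = -0.35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_length < 18:
            raise SpecError("stem_length must be >= 18 so arm reads fit the 18-25 nt range")
        if self.loop_length < 3:
            raise SpecError("loop_length must be >= 3")
        if min(self.mature_reads_0mm, self.star_reads_0mm) < 0:
            raise SpecError("read counts must be >= 0")
        if not 0 < self.homogeneity_target <= 1:
            raise SpecError("homogeneity_target must lie in (0, 1]")
        if self.n_subhairpins < 1:
            raise SpecError("n_subhairpins must be >= 1")
        if self.overhang_3p < -3:
            raise SpecError("recessed 3' ends beyond 3 nt leave the overhang undefined")


def _hairpin_structure(spec: HairpinSimSpec) -> str:
    prefix = "." * max(0, -spec.overhang_3p)
    suffix = "." * max(0, spec.overhang_3p)
    if spec.n_subhairpins == 1:
        middle = "." * spec.loop_length
    else:
        unit = "((((...))))"
        middle = "." + ".".join([unit] * spec.n_subhairpins) + "."
    return prefix + "(" * spec.stem_length + middle + ")" * spec.stem_length + suffix


def _sequence_for_structure(dot_bracket: str, rng: np.random.Generator) -> str:
    from bamir.novel_mirna_filter import pair_table

    partner = pair_table(dot_bracket)
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    seq = [""] * len(dot_bracket)
    for i, j in enumerate(partner):
        if seq[i]:
            continue
        seq[i] = str(rng.choice(_NT))
        if j >= 0:
            seq[j] = comp[seq[i]]
    return "".join(seq)


def _stack_reads(
    total: int, anchor: int, homogeneity: float, read_length: int
) -> tuple[list[AlignedRead], float]:
    """Collapsed 0-mismatch reads with the modal 5' start at ``anchor``.

    Returns the reads and the realised modal fraction; raises
    :class:`SpecError` if the target fraction cannot be realised with the
    available alternative start positions.
    """
    if total == 0:
        return [], 0.0
    modal = max(1, round(homogeneity * total))
    rest = total - modal
    alt = [rest // 3 + (1 if i < rest % 3 else 0) for i in range(3)]
    if max(alt, default=0) > modal:
        raise SpecError(
            f"homogeneity_target {homogeneity} unreachable with {total} reads "
            "spread over 3 alternative start positions"
        )
    reads = [AlignedRead(anchor, anchor + read_length, 0, modal)]
    for offset, count in enumerate(alt, start=1):
        if count > 0:
            reads.append(AlignedRead(anchor + offset, anchor + offset + read_length, 0, count))
    return reads, modal / total


def simulate_hairpin_candidate(
    spec: HairpinSimSpec,
) -> tuple[HairpinCandidate, list[AlignedRead], dict]:
    """Generate one candidate precursor, its read stack and truth labels.

    The mature arm is the 5' arm; the star arm is the 3' arm.  Truth holds
    the per-criterion pass/fail decisions implied by the spec (thresholds
    ≥30 / ≥10 / ≥0.5 / overhang 0-4 / MFE ≤ −0.2 per nt / one loop),
    the realised homogeneity, and the arm label of every emitted read.
    """
    rng = np.random.default_rng(spec.rng_seed)
    dot_bracket = _hairpin_structure(spec)
    sequence = _sequence_for_structure(dot_bracket, rng)
    n = len(sequence)
    prefix = max(0, -spec.overhang_3p)
    middle_len = n - prefix - 2 * spec.stem_length - max(0, spec.overhang_3p)
    mature_arm = (0, prefix + spec.stem_length)
    star_arm = (prefix + spec.stem_length + middle_len, n)

    # one-decimal MFE, as folding tools print it; the truth label below uses
    # the realised per-nucleotide value of the emitted candidate
    mfe = round(spec.mfe_per_nt_target * n, 1)
    candidate = HairpinCandidate(
        f"hp_seed{spec.rng_seed}", sequence, dot_bracket, mfe, mature_arm, star_arm
    )

    read_length = min(22, spec.stem_length)
    mature_reads, realised_h = _stack_reads(
        spec.mature_reads_0mm, mature_arm[0], spec.homogeneity_target, read_length
    )
    star_len = min(22, n - star_arm[0])
    star_reads, _ = _stack_reads(spec.star_reads_0mm, star_arm[0], 1.0, star_len)
    reads = mature_reads + star_reads

    truth = {
        "criteria": {
            "mature_support": spec.mature_reads_0mm >= 30,
            "star_support": spec.star_reads_0mm >= 10,
            "homogeneity": spec.mature_reads_0mm > 0 and realised_h >= 0.5,
            "overhang": 0 <= spec.overhang_3p <= 4,
            "mfe_per_nt": mfe / n <= -0.2,
            "hairpin_loops": spec.n_subhairpins <= 1,
        },
        "homogeneity_value": realised_h,
        "overhang_value": spec.overhang_3p,
        "read_arms": ["mature"] * len(mature_reads) + ["star"] * len(star_reads),
    }
    truth["overall_pass"] = all(truth["criteria"].values())
    return candidate, reads, truth


# ---------------------------------------------------------------------------
# 3'UTRs with planted seed-match sites


@dataclass(frozen=True)
class UTRSimSpec:
    utr_length: int = 300
    planted_sites: tuple[tuple[str, int], ...] = ()
    background_gc: float = 0.45
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.utr_length < 8:
            raise SpecError("utr_length must be >= 8")
        if not 0 < self.background_gc < 1:
            raise SpecError("background_gc must lie in (0, 1)")
        spans = sorted((pos, pos + 8) for _, pos in self.planted_sites)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise SpecError("planted sites overlap")
        for cls, pos in self.planted_sites:
            if pos < 0 or pos + 8 > self.utr_length:
                raise SpecError(f"site at {pos} does not fit in utr_length {self.utr_length}")


def _site_window(mirna_seq: str, site_class: str, rng: np.random.Generator) -> str:
    """The exact 8-nt target window (5'->3') realising one site class."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}

    def not_in(excluded: set[str]) -> str:
        choices = [x for x in "ACGU" if x not in excluded]
        return str(rng.choice(np.array(choices)))

    seed_rc = reverse_complement(mirna_seq[1:8])  # complements m8..m2, read 5'->3'
    core_rc = reverse_complement(mirna_seq[1:7])  # complements m7..m2
    if site_class == "8mer":
        return seed_rc + "A"
    if site_class == "7mer-m8":
        return seed_rc + not_in({"A"})
    if site_class == "7mer-A1":
        return not_in({comp[mirna_seq[7]]}) + core_rc + "A"
    if site_class == "6mer":
        return not_in({comp[mirna_seq[7]]}) + core_rc + not_in({"A"})
    if site_class == "off-6mer":
        off_rc = reverse_complement(mirna_seq[2:8])  # complements m8..m3
        return off_rc + not_in({comp[mirna_seq[1]]}) + str(rng.choice(_NT))
    raise SpecError(f"unknown site class {site_class!r}")


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_NT, size=length, p=probs)


def _assemble_utr(
    gene_id: str,
    length: int,
    gc: float,
    planted: list[tuple[SequenceRecord, str, int]],
    scan_against: list[SequenceRecord],
    rng: np.random.Generator,
) -> tuple[SequenceRecord, list[Site]]:
    """Background + planted windows, resampled until no accidental site.

    ``planted`` holds (mirna, class, position) triples; ``scan_against``
    is the full miRNA panel the cleanliness scan must consider.
    """
    windows = {}
    for mirna, site_class, pos in planted:
        windows[(mirna.id, pos)] = _site_window(mirna.sequence, site_class, rng)
    planted_keys = {(m.id, pos) for m, _, pos in planted}

    for _ in range(_MAX_BACKGROUND_ATTEMPTS):
        chars = _random_background(length, gc, rng)
        for (mirna_id, pos), window in windows.items():
            chars[pos : pos + 8] = list(window)
        seq = "".join(chars)
        clean = True
        for mirna in scan_against:
            for pos in range(length - 7):
                cls = classify_seed_site(mirna, seq[pos : pos + 8])
                if cls is not None and (mirna.id, pos) not in planted_keys:
                    clean = False
                    break
            if not clean:
                break
        if clean:
            truth = [
                Site(gene_id, mirna.id, pos, site_class)
                for mirna, site_class, pos in sorted(planted, key=lambda t: t[2])
            ]
            return SequenceRecord(gene_id, seq), truth
    raise SpecError(
        f"{gene_id}: could not realise a background free of accidental sites "
        f"in {_MAX_BACKGROUND_ATTEMPTS} attempts"
    )


def simulate_utr_with_sites(
    mirna: SequenceRecord, spec: UTRSimSpec
) -> tuple[SequenceRecord, list[Site]]:
    """A 3'UTR whose only seed-match sites for ``mirna`` are the planted ones.

    Each planted window is the exact reverse-complement pattern defining
    its class; the background is resampled (up to 100 attempts) whenever it
    spawns an accidental classifiable window, so the returned truth sites
    are exactly the sites present.
    """
    if len(mirna) < 8:
        raise SpecError("miRNA must be >= 8 nt")
    rng = np.random.default_rng(spec.rng_seed)
    planted = [(mirna, cls, pos) for cls, pos in spec.planted_sites]
    return _assemble_utr(
        f"utr_seed{spec.rng_seed}", spec.utr_length, spec.background_gc, planted, [mirna], rng
    )


# ---------------------------------------------------------------------------
# count matrices


@dataclass(frozen=True)
class CountSimSpec:
    n_genes: int = 2000
    de_fraction: float = 0.1
    log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    library_size_mean: float = 2_000_000.0
    rng_seed: int = 0
    # domain receiving the planted effect, versus the other two
    de_domain: str = "PBA/OFT"

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise SpecError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SpecError("nb_dispersion must be > 0")


DESIGN_DOMAINS = ("BA1", "BA2", "PBA/OFT")
DESIGN_STAGES = ("E10.5", "E11.5")
DESIGN_REPLICATES = (1, 2)


def design_metadata() -> pd.DataFrame:
    """The fixed 3-domain × 2-stage × 2-replicate library layout."""
    rows = [
        {
            "library_id": f"{d.replace('/', '')}_{s}_r{r}",
            "domain": d,
            "stage": s,
            "replicate": r,
        }
        for d in DESIGN_DOMAINS
        for s in DESIGN_STAGES
        for r in DESIGN_REPLICATES
    ]
    return pd.DataFrame(rows).set_index("library_id")


def simulate_count_matrix(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with fold changes planted in one domain.

    Returns (counts, library metadata, truth).  Truth has one row per gene
    with ``is_de`` and ``true_log2fc`` (the planted log2 fold change of
    the focal domain versus the other two; 0 for non-DE genes).
    """
    rng = np.random.default_rng(spec.rng_seed)
    meta = design_metadata()
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]

    base_mean = rng.lognormal(mean=4.0, sigma=1.4, size=spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = np.zeros(spec.n_genes)
    true_lfc[de_idx] = signs * spec.log2fc_magnitude

    in_domain = (meta["domain"] == spec.de_domain).to_numpy()
    mu = np.outer(base_mean, np.ones(len(meta)))
    mu[:, in_domain] *= 2.0 ** true_lfc[:, None]
    # scale each library to the requested expected depth
    mu *= spec.library_size_mean / mu.sum(axis=0, keepdims=True)

    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=meta.index)
    truth = pd.DataFrame(
        {"gene_id": genes, "is_de": true_lfc != 0, "true_log2fc": true_lfc}
    )
    return matrix, meta.copy(), truth


# ---------------------------------------------------------------------------
# interactomes


@dataclass(frozen=True)
class InteractomeSimSpec:
    n_mirnas: int = 50
    n_genes: int = 2000
    set_size: int = 300
    baseline_target_prob: float = 0.05
    enriched_mirna_id: str | None = None  # default: first miRNA when factor > 1
    enrichment_factor: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size > self.n_genes:
            raise SpecError("set_size must be <= n_genes")
        if not 0 < self.baseline_target_prob < 1:
            raise SpecError("baseline_target_prob must lie in (0, 1)")
        if self.enrichment_factor < 1:
            raise SpecError("enrichment_factor must be >= 1")


SITE_CLASS_CHOICES = np.array(["8mer", "7mer-m8", "7mer-A1"])


def _sample_interactions(
    rng: np.random.Generator,
    mirna_ids: list[str],
    gene_ids: list[str],
    set_genes: set[str],
    baseline: float,
    enrichment_factor: float,
    planted_id: str | None,
) -> pd.DataFrame:
    """Bernoulli interaction table: every (miRNA, gene) pair targeted with
    the baseline probability, except the planted miRNA's set genes which
    are targeted with min(1, enrichment_factor × baseline)."""
    probs = np.full((len(mirna_ids), len(gene_ids)), baseline)
    in_set = np.array([g in set_genes for g in gene_ids])
    if planted_id is not None:
        probs[mirna_ids.index(planted_id), in_set] = min(1.0, enrichment_factor * baseline)
    hits = rng.random(probs.shape) < probs
    mi, gi = np.nonzero(hits)
    n_rows = len(mi)
    return pd.DataFrame(
        {
            "mirna_id": [mirna_ids[i] for i in mi],
            "gene_id": [gene_ids[j] for j in gi],
            "n_sites": np.full(n_rows, 2, dtype=int),
            "best_class": rng.choice(SITE_CLASS_CHOICES, size=n_rows),
            "min_energy": np.round(-7.0 - 8.0 * rng.random(n_rows), 2),
        }
    )


def simulate_interactome(
    spec: InteractomeSimSpec,
) -> tuple[pd.DataFrame, "object", str | None]:
    """An interaction table with one miRNA enriched for a planted gene set.

    Returns (interactions, GeneSet, enriched miRNA id).  With
    ``enrichment_factor == 1`` no miRNA is planted and the truth id is
    None — the null configuration for calibration checks.
    """
    from bamir.target_enrichment import GeneSet

    rng = np.random.default_rng(spec.rng_seed)
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(spec.n_mirnas)]
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    set_genes = set(rng.choice(np.array(gene_ids), size=spec.set_size, replace=False))
    if spec.enrichment_factor == 1:
        planted = None
    else:
        planted = spec.enriched_mirna_id or mirna_ids[0]
        if planted not in mirna_ids:
            raise SpecError(f"enriched_mirna_id {planted!r} not among generated miRNAs")
    table = _sample_interactions(
        rng, mirna_ids, gene_ids, set_genes,
        spec.baseline_target_prob, spec.enrichment_factor, planted,
    )
    return table, GeneSet("planted", frozenset(set_genes)), planted
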