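"""Emit a complete, internally consistent toy dataset directory.

The directory holds every input the end-to-end pipeline consumes — counts
with library metadata, per-comparison DE tables, a GO enrichment table
with gene annotation, a miRNA panel, 3'UTRs with planted target sites,
and hairpin-candidate fixtures for the novel-miRNA filter — plus a
``truth.json`` with the planted ground truth and a ready-to-run
``config.yaml``.

The planted structure ties the stages together: the genes up-regulated in
the posterior domain of the simulated count matrix form the domain gene
set (the DE tables and GO annotation are written to reproduce exactly
that set), and one miRNA of the panel has its interactions with those
genes boosted, so the enrichment stage should rank it first.  Each
realised miRNA→gene interaction is physically planted as two strong seed
sites (an 8mer and a 7mer-m8) in that gene's UTR, with backgrounds
resampled until no accidental site exists, so sequence-level target
prediction recovers the planted interactome exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bamir.io_formats import (
    SequenceRecord,
    StructureRecord,
    reverse_complement,
    write_arm_table,
    write_counts_table,
    write_de_table,
    write_fasta,
    write_interactions_table,
    write_read_stacks,
    write_structure_file,
)
from bamir.synthetic_data import (
    CountSimSpec,
    HairpinSimSpec,
    SpecError,
    _assemble_utr,
    _sample_interactions,
    _site_window,
    simulate_count_matrix,
    simulate_hairpin_candidate,
)
from bamir.target_prediction import EnergyConfig, classify_seed_site, duplex_energy

logger = logging.getLogger(__name__)

_NT = np.array(list("ACGU"))

# hairpin fixtures spanning pass and every single-criterion failure
_HAIRPIN_SPECS = {
    "all_pass": dict(),
    "weak_mature": dict(mature_reads_0mm=12),
    "weak_star": dict(star_reads_0mm=9),
    "ragged_5p": dict(homogeneity_target=0.4),
    "long_overhang": dict(overhang_3p=6),
    "weak_fold": dict(mfe_per_nt_target=-0.12),
    "branched": dict(n_subhairpins=2),
}


def _deterministic_clash(a: SequenceRecord, b: SequenceRecord) -> bool:
    """True if a planted seed window for ``a`` must always contain a
    classifiable pattern for ``b`` regardless of the surrounding background.

    The emitter plants windows of the form rc(seed of a) + x.  A window
    shifted into such planted content classifies for ``b`` whenever one of
    b's defining patterns (7-nt seed match, 6-nt core match, 6-nt offset
    match) occurs wholly inside it — background resampling can never fix
    that, so such seed pairs are rejected outright.  For ``a == b`` the
    designed occurrences at their canonical offsets are permitted.
    """
    pats_b = {
        "seed7": reverse_complement(b.sequence[1:8]),
        "core6": reverse_complement(b.sequence[1:7]),
        "off6": reverse_complement(b.sequence[2:8]),
    }
    allowed = {("seed7", 0), ("core6", 1), ("off6", 0)} if a.id == b.id else set()
    for x in "ACGU":
        window = reverse_complement(a.sequence[1:8]) + x
        for name, pat in pats_b.items():
            for off in range(len(window) - len(pat) + 1):
                if window[off : off + len(pat)] == pat and (name, off) not in allowed:
                    return True
    return False


def _simulate_mirna_panel(
    n: int, rng: np.random.Generator, length: int = 22
) -> list[SequenceRecord]:
    """miRNAs with GC-rich, mutually non-cross-matching seeds.

    GC-rich seeds keep every planted seed helix below the −7 kcal/mol
    retention cutoff; the pairwise clash check guarantees that planted
    windows can never deterministically spawn a site for another panel
    member (or a shifted one for their own miRNA).
    """
    panel: list[SequenceRecord] = []
    guard = 0
    while len(panel) < n:
        guard += 1
        if guard > 500 * n:
            raise SpecError("could not assemble a non-cross-matching miRNA panel")
        seed = "".join(rng.choice(_NT, size=7, p=[0.1, 0.4, 0.4, 0.1]))
        seq = (
            str(rng.choice(_NT))
            + seed
            + "".join(rng.choice(_NT, size=length - 8))
        )
        cand = SequenceRecord(f"mir-{len(panel) + 1:03d}", seq)
        # seed helix alone must clear the retention threshold with margin
        helix = duplex_energy(cand.sequence, _site_window(cand.sequence, "8mer", rng),
                              EnergyConfig(seed_region_only=True))
        if helix > -7.5:
            continue
        if _deterministic_clash(cand, cand):
            continue
        if any(
            _deterministic_clash(cand, other) or _deterministic_clash(other, cand)
            for other in panel
        ):
            continue
        panel.append(cand)
    return panel


def simulate_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 80,
    n_mirnas: int = 8,
    de_fraction: float = 0.35,
    baseline_target_prob: float = 0.07,
    enrichment_factor: float = 8.0,
) -> dict:
    """Write a toy dataset directory; returns the planted truth.

    See the module docstring for how the pieces cohere.  Everything is a
    deterministic function of ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- counts and the planted up-regulated gene set -------------------
    cspec = CountSimSpec(
        n_genes=n_genes,
        de_fraction=de_fraction,
        log2fc_magnitude=1.5,
        nb_dispersion=0.05,
        library_size_mean=200_000.0,
        rng_seed=seed,
    )
    counts, meta, count_truth = simulate_count_matrix(cspec)
    write_counts_table(counts, out / "counts.tsv")
    meta.to_csv(out / "library_meta.tsv", sep="\t", index_label="library_id")

    set_genes = sorted(count_truth.loc[count_truth["true_log2fc"] > 0, "gene_id"])
    gene_ids = list(count_truth["gene_id"])

    # --- DE tables reproducing the planted set in both comparisons ------
    for name in ("de_pbaoft_vs_ba1.tsv", "de_pbaoft_vs_ba2.tsv"):
        noise = rng.normal(0.0, 0.05, size=n_genes)
        lfc = count_truth["true_log2fc"].to_numpy() + noise
        padj = np.where(count_truth["is_de"], 10.0 ** rng.uniform(-6, -2, n_genes),
                        rng.uniform(0.2, 1.0, n_genes))
        write_de_table(
            pd.DataFrame({"gene_id": gene_ids, "log2fc": np.round(lfc, 4),
                          "padj": np.round(padj, 6)}),
            out / name,
        )

    # --- GO tables: one strongly enriched term carries the set ----------
    pd.DataFrame(
        {
            "term_id": ["GO:TOY0001", "GO:TOY0002"],
            "name": ["posterior arch development", "housekeeping"],
            "fold_enrichment": [5.2, 1.2],
            "fdr": [1e-4, 0.4],
        }
    ).to_csv(out / "go_terms.tsv", sep="\t", index=False)
    non_set = [g for g in gene_ids if g not in set_genes]
    annotation = [("GO:TOY0001", g) for g in set_genes] + [
        ("GO:TOY0002", g) for g in non_set[: len(non_set) // 2]
    ]
    pd.DataFrame(annotation, columns=["term_id", "gene_id"]).to_csv(
        out / "go_annotation.tsv", sep="\t", index=False
    )

    # --- miRNA panel and planted interactome ----------------------------
    mirnas = _simulate_mirna_panel(n_mirnas, rng)
    write_fasta(mirnas, out / "mirnas.fasta")
    planted_mirna = mirnas[0].id
    interactions = _sample_interactions(
        rng,
        [m.id for m in mirnas],
        gene_ids,
        set(set_genes),
        baseline_target_prob,
        enrichment_factor,
        planted_mirna,
    )

    # --- UTRs with the interactome planted as real seed sites -----------
    by_gene: dict[str, list[str]] = {}
    for row in interactions.itertuples():
        by_gene.setdefault(row.gene_id, []).append(row.mirna_id)
    mirna_by_id = {m.id: m for m in mirnas}
    utrs: list[SequenceRecord] = []
    min_energy: dict[tuple[str, str], float] = {}
    ecfg = EnergyConfig()
    for gene_id in gene_ids:
        partners = by_gene.get(gene_id, [])
        planted = []
        pos = 10
        for mirna_id in partners:
            for cls in ("8mer", "7mer-m8"):
                planted.append((mirna_by_id[mirna_id], cls, pos))
                pos += 24
        length = max(120, pos + 40)
        utr, truth_sites = _assemble_utr(
            gene_id, length, 0.45, planted, mirnas, rng
        )
        utrs.append(utr)
        for site in truth_sites:
            region = utr.sequence[max(0, site.utr_position - ecfg.upstream_extension)
                                  : site.utr_position + 8]
            e = duplex_energy(mirna_by_id[site.mirna_id].sequence, region, ecfg)
            key = (site.mirna_id, gene_id)
            min_energy[key] = min(min_energy.get(key, 0.0), e)
    write_fasta(utrs, out / "utrs.fasta")

    interactions = interactions.assign(
        best_class="8mer",
        min_energy=[
            round(min_energy[(r.mirna_id, r.gene_id)], 2) for r in interactions.itertuples()
        ],
    )
    write_interactions_table(interactions, out / "interactions.tsv")

    # --- hairpin fixtures for the novel-miRNA filter --------------------
    structures, arm_rows, read_rows, hairpin_truth = [], [], [], {}
    for i, (label, overrides) in enumerate(_HAIRPIN_SPECS.items()):
        hspec = HairpinSimSpec(rng_seed=seed * 1000 + i, **overrides)
        cand, reads, truth = simulate_hairpin_candidate(hspec)
        cand_id = f"{label}_{cand.id}"
        structures.append(
            StructureRecord(cand_id, cand.sequence, cand.dot_bracket, cand.mfe_kcal_mol)
        )
        arm_rows.append(
            {"precursor_id": cand_id,
             "mature_start": cand.mature_arm[0], "mature_end": cand.mature_arm[1],
             "star_start": cand.star_arm[0], "star_end": cand.star_arm[1]}
        )
        for r in reads:
            read_rows.append({"precursor_id": cand_id, "start": r.start, "end": r.end,
                              "mismatches": r.mismatches, "count": r.count})
        hairpin_truth[cand_id] = truth["criteria"] | {"overall_pass": truth["overall_pass"]}
    write_structure_file(structures, out / "structures.txt")
    write_arm_table(pd.DataFrame(arm_rows).set_index("precursor_id"), out / "arms.tsv")
    write_read_stacks(pd.DataFrame(read_rows), out / "read_stacks.tsv")

    truth = {
        "seed": seed,
        "enriched_mirna": planted_mirna,
        "gene_set": set_genes,
        "interactions": sorted(
            map(list, zip(interactions["mirna_id"], interactions["gene_id"]))
        ),
        "hairpins": hairpin_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    config = {
        "seed": seed,
        "assay": "rna",
        "inputs": {
            "counts": "counts.tsv",
            "library_meta": "library_meta.tsv",
            "de_vs_ba1": "de_pbaoft_vs_ba1.tsv",
            "de_vs_ba2": "de_pbaoft_vs_ba2.tsv",
            "go_terms": "go_terms.tsv",
            "go_annotation": "go_annotation.tsv",
            "mirnas": "mirnas.fasta",
            "utrs": "utrs.fasta",
        },
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return truth
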