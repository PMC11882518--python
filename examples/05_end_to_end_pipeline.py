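"""The full pipeline on a simulated toy dataset directory.

Writes a complete dataset (counts, DE tables, GO tables, miRNA and UTR
FASTAs with physically planted target sites), runs expression filtering,
sequence-level target prediction, gene-set construction and enrichment
ranking, and compares the outcome with the planted truth.
"""

import tempfile
from pathlib import Path

from bamir.datasets import simulate_dataset
from bamir.pipeline import load_config, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    toy = Path(tmp) / "toy"
    truth = simulate_dataset(toy, seed=3)
    print(f"toy dataset: {len(truth['gene_set'])} planted set genes, "
          f"{len(truth['interactions'])} planted interactions, "
          f"enriched miRNA {truth['enriched_mirna']}")

    ranking = run_pipeline(load_config(toy / "config.yaml"), Path(tmp) / "run")
    print("\nenrichment ranking (top 3):")
    print(ranking.head(3).to_string(index=False,
          formatters={"p_hyper": "{:.4f}".format,
                      "fold_enrichment": "{:.2f}".format,
                      "bh_fdr": "{:.3g}".format}))

    top = ranking.iloc[0]
    ok = top["mirna_id"] == truth["enriched_mirna"]
    print(f"\nTop-ranked miRNA {top['mirna_id']} "
          f"{'matches' if ok else 'does NOT match'} the planted truth.")
    print("Every interaction the ranking uses was recovered from sequence:")
    print("the planted sites were rediscovered by the seed scan, passed the")
    print("energy and site-count filters, and aggregated per (miRNA, gene).")
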