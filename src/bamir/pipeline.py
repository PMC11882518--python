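"""End-to-end orchestration: expression → targets → gene set → enrichment.

A single YAML config carries every stage's thresholds and input paths so
the study defaults live in one versioned place.  Unknown keys are
rejected before any stage runs.  Each run writes its stage outputs plus a
``manifest.json`` recording the resolved config, a config hash, input
checksums and the package version; rerunning on identical inputs is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import bamir
from bamir.expression_analysis import ExpressionConfig, cpm, expressed_genes
from bamir.io_formats import (
    parse_fasta,
    read_counts_table,
    read_de_table,
    read_library_metadata,
    _read_tsv,
    write_interactions_table,
)
from bamir.target_enrichment import GeneSetConfig, build_domain_gene_set, mirna_set_enrichment
from bamir.target_prediction import (
    EnergyConfig,
    PredictionConfig,
    filter_interactions,
    predict_targets,
    sites_to_frame,
)

logger = logging.getLogger(__name__)

INPUT_KEYS = (
    "counts",
    "library_meta",
    "de_vs_ba1",
    "de_vs_ba2",
    "go_terms",
    "go_annotation",
    "mirnas",
    "utrs",
)


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a pipeline config."""


@dataclass(frozen=True)
class PipelineConfig:
    inputs: dict[str, Path]
    seed: int = 0
    assay: str = "rna"
    universe: str = "interactions"
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    gene_set: GeneSetConfig = field(default_factory=GeneSetConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        d["prediction"]["drop_classes"] = sorted(self.prediction.drop_classes)
        return d


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    if cls is PredictionConfig:
        mapping = dict(mapping)
        if "drop_classes" in mapping:
            mapping["drop_classes"] = frozenset(mapping["drop_classes"])
        if "energy" in mapping:
            mapping["energy"] = _build_section(EnergyConfig, mapping["energy"], "prediction.energy")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' config: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML; paths resolve against its directory."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known_top = {"inputs", "seed", "assay", "universe", "expression", "prediction", "gene_set"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if "inputs" not in raw:
        raise ConfigError(f"{path}: missing 'inputs' section")
    unknown_inputs = set(raw["inputs"]) - set(INPUT_KEYS)
    if unknown_inputs:
        raise ConfigError(f"{path}: unknown input key(s) {sorted(unknown_inputs)}")
    missing = set(INPUT_KEYS) - set(raw["inputs"])
    if missing:
        raise ConfigError(f"{path}: missing input path(s) {sorted(missing)}")
    inputs = {k: (path.parent / v).resolve() for k, v in raw["inputs"].items()}
    for key, p in inputs.items():
        if not p.exists():
            raise ConfigError(f"{path}: input '{key}' does not exist: {p}")
    return PipelineConfig(
        inputs=inputs,
        seed=int(raw.get("seed", 0)),
        assay=str(raw.get("assay", "rna")),
        universe=str(raw.get("universe", "interactions")),
        expression=_build_section(ExpressionConfig, raw.get("expression", {}), "expression"),
        prediction=_build_section(PredictionConfig, raw.get("prediction", {}), "prediction"),
        gene_set=_build_section(GeneSetConfig, raw.get("gene_set", {}), "gene_set"),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run all stages on a dataset directory; returns the ranked enrichment.

    Outputs written under ``out_dir``: expressed_genes.txt, cpm.tsv,
    sites.tsv, interactions.tsv, gene_set.txt, enrichment.tsv and
    manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/4: expression filtering")
    counts = read_counts_table(config.inputs["counts"])
    meta = read_library_metadata(config.inputs["library_meta"])
    if not set(counts.columns) <= set(meta.index):
        raise ValueError("count matrix has libraries absent from the metadata")
    expressed = expressed_genes(counts, config.expression, assay=config.assay)
    cpm(counts).round(4).to_csv(out / "cpm.tsv", sep="\t", index_label="gene_id")
    (out / "expressed_genes.txt").write_text("".join(f"{g}\n" for g in sorted(expressed)))

    logger.info("stage 2/4: target prediction (%d expressed genes)", len(expressed))
    mirnas = parse_fasta(config.inputs["mirnas"])
    utrs = [u for u in parse_fasta(config.inputs["utrs"]) if u.id in expressed]
    sites = predict_targets(mirnas, utrs, config.prediction.energy)
    sites_to_frame(sites).to_csv(out / "sites.tsv", sep="\t", index=False)
    interactions = filter_interactions(sites, config.prediction)
    write_interactions_table(interactions, out / "interactions.tsv")

    logger.info("stage 3/4: domain gene set")
    gene_set = build_domain_gene_set(
        read_de_table(config.inputs["de_vs_ba1"]),
        read_de_table(config.inputs["de_vs_ba2"]),
        _read_tsv(config.inputs["go_terms"], ["term_id", "fold_enrichment", "fdr"]),
        _read_tsv(config.inputs["go_annotation"], ["term_id", "gene_id"]),
        config.gene_set,
    )
    (out / "gene_set.txt").write_text("".join(f"{g}\n" for g in sorted(gene_set.genes)))

    logger.info("stage 4/4: enrichment ranking (%d interactions, %d set genes)",
                len(interactions), len(gene_set))
    ranking = mirna_set_enrichment(interactions, gene_set, universe=config.universe)
    ranking.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "package_version": bamir.__version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {k: _sha256(p) for k, p in sorted(config.inputs.items())},
        "outputs": [
            "cpm.tsv", "expressed_genes.txt", "sites.tsv", "interactions.tsv",
            "gene_set.txt", "enrichment.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return ranking
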