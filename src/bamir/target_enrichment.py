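"""Candidate-miRNA ranking by hypergeometric gene-set enrichment.

The domain gene set collects genes up-regulated (>1.5-fold, adjusted
p ≤ 0.05) in the posterior-arch/outflow-tract domain relative to both
anterior arches, restricted to genes annotated under the strongly enriched
GO terms (≥2-fold, FDR ≤ 0.05) of an externally computed enrichment table.

Each miRNA is then scored by the upper-tail hypergeometric probability of
its predicted interactions with set genes: with the full interaction list
as the population (N rows, K of them touching set genes) and the miRNA's
own n interactions as the sample containing k set-gene interactions,

    p = P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

and fold enrichment (k/n)/(K/N).  miRNAs are ranked by ascending p.  The
raw p drives the ranking; a Benjamini-Hochberg column is emitted alongside
for transparency.  A gene-level urn (N = genes in the universe, K = set
size) is available as an alternative parameterisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetConfig:
    up_fold_min: float = 1.5  # strictly above, as stated
    up_padj_max: float = 0.05
    go_fold_min: float = 2.0
    go_fdr_max: float = 0.05


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), inclusive of the observed k."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent urn counts k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def build_domain_gene_set(
    de_vs_ba1: pd.DataFrame,
    de_vs_ba2: pd.DataFrame,
    go_terms: pd.DataFrame,
    go_annotation: pd.DataFrame,
    config: GeneSetConfig | None = None,
    label: str = "PBA/OFT",
) -> GeneSet:
    """Intersect domain-up-regulated genes with top-GO-term annotation.

    ``de_vs_ba1`` / ``de_vs_ba2`` are DE tables (gene_id, log2fc, padj)
    with positive log2fc meaning higher in the focal domain; ``go_terms``
    has columns (term_id, fold_enrichment, fdr) and ``go_annotation``
    (gene_id, term_id).  A gene enters the set iff it is up in BOTH
    comparisons and annotated to at least one passing term.
    """
    cfg = config or GeneSetConfig()
    lfc_min = math.log2(cfg.up_fold_min)

    def up(de: pd.DataFrame) -> set[str]:
        ok = (de["log2fc"] > lfc_min) & (de["padj"] <= cfg.up_padj_max)
        return set(de.loc[ok, "gene_id"])

    up_both = up(de_vs_ba1) & up(de_vs_ba2)
    passing = go_terms[
        (go_terms["fold_enrichment"] >= cfg.go_fold_min) & (go_terms["fdr"] <= cfg.go_fdr_max)
    ]
    if passing.empty:
        logger.warning("no GO terms pass fold >= %g, FDR <= %g; gene set is empty",
                       cfg.go_fold_min, cfg.go_fdr_max)
        return GeneSet(label, frozenset())
    annotated = set(
        go_annotation.loc[go_annotation["term_id"].isin(set(passing["term_id"])), "gene_id"]
    )
    return GeneSet(label, frozenset(up_both & annotated))


def mirna_set_enrichment(
    interactions: pd.DataFrame,
    gene_set: GeneSet,
    universe: str = "interactions",
) -> pd.DataFrame:
    """Rank miRNAs by hypergeometric enrichment of set-gene interactions.

    ``interactions`` holds one row per (mirna_id, gene_id).  With the
    default interaction-level urn, N is the total row count and K the rows
    whose gene is in the set; per miRNA, n is its row count and k its
    set-gene rows.  ``universe='genes'`` instead draws from the gene
    universe (N = distinct genes, K = set genes present, n = genes the
    miRNA targets, k = set genes it targets).

    Returns columns (mirna_id, k, n, K, N, p_hyper, fold_enrichment,
    bh_fdr), sorted by ascending p, ties broken by descending fold then id.
    """
    if interactions.duplicated(subset=["mirna_id", "gene_id"]).any():
        raise ValueError("interactions must be aggregated to one row per (miRNA, gene)")
    if universe not in ("interactions", "genes"):
        raise ValueError(f"unknown universe {universe!r}")
    in_set = interactions["gene_id"].isin(gene_set.genes)
    if universe == "interactions":
        N = len(interactions)
        K = int(in_set.sum())
        per = interactions.assign(in_set=in_set).groupby("mirna_id")["in_set"]
        n_by = per.size()
        k_by = per.sum()
    else:
        genes = interactions["gene_id"].unique()
        N = len(genes)
        K = sum(g in gene_set.genes for g in genes)
        grouped = interactions.groupby("mirna_id")["gene_id"]
        n_by = grouped.nunique()
        k_by = grouped.apply(lambda g: g[g.isin(gene_set.genes)].nunique())
    if N == 0:
        raise ValueError("empty interaction table")

    rows = []
    for mirna_id in n_by.index:
        n = int(n_by[mirna_id])
        k = int(k_by[mirna_id])
        p = hypergeom_upper_tail(k, n, K, N)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        rows.append({"mirna_id": mirna_id, "k": k, "n": n, "K": K, "N": N,
                     "p_hyper": p, "fold_enrichment": fold})
    result = pd.DataFrame(rows)
    result["bh_fdr"] = multipletests(result["p_hyper"], method="fdr_bh")[1]
    result = result.sort_values(
        by=["p_hyper", "fold_enrichment", "mirna_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return result
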