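"""Expression thresholding, DE-table filtering and descriptive statistics.

Counts are normalised to CPM (counts per million, each library scaled to
sum to 10^6).  A gene counts as expressed when its CPM exceeds the assay
threshold (4.2 for small RNA-seq ≈ 100 reads, 0.38 for RNA-seq ≈ 10
reads) in at least two libraries — strictly above, per the stated rule.
Differential expression keeps records with at least a 1.5-fold change in
either direction and adjusted p ≤ 0.05, both boundaries inclusive.

Also here: UpSet-style exclusive overlap counts between DE sets, row
z-scoring for heatmaps, Spearman library-correlation matrices, and the
2^-ΔΔCt relative-quantification formula for qPCR fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DOMAINS = ("BA1", "BA2", "PBA/OFT")
STAGES = ("E10.5", "E11.5")


@dataclass(frozen=True)
class ExpressionConfig:
    cpm_threshold_small_rna: float = 4.2
    cpm_threshold_rna: float = 0.38
    min_libraries: int = 2
    fold_change_min: float = 1.5
    padj_max: float = 0.05
    # boundary behaviour of the CPM rule; the stated rule is strict "above"
    cpm_inclusive: bool = False

    def threshold_for(self, assay: str) -> float:
        if assay == "small_rna":
            return self.cpm_threshold_small_rna
        if assay == "rna":
            return self.cpm_threshold_rna
        raise ValueError(f"unknown assay {assay!r}; expected 'small_rna' or 'rna'")


def cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each library column scaled to sum to 10^6."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum library column(s): {list(zero.index)}")
    return matrix / sums * 1_000_000


def expressed_genes(
    matrix: pd.DataFrame, config: ExpressionConfig | None = None, assay: str = "small_rna"
) -> set[str]:
    """Genes whose CPM clears the assay threshold in >= min_libraries libraries."""
    cfg = config or ExpressionConfig()
    threshold = cfg.threshold_for(assay)
    values = cpm(matrix)
    above = values >= threshold if cfg.cpm_inclusive else values > threshold
    keep = above.sum(axis=1) >= cfg.min_libraries
    return set(matrix.index[keep])


def filter_de(records: pd.DataFrame, config: ExpressionConfig | None = None) -> pd.DataFrame:
    """Keep DE rows with |log2fc| >= log2(fold_change_min) and padj <= padj_max.

    Rows with missing padj (the independent-filtering NA convention) are
    dropped with a log message.
    """
    cfg = config or ExpressionConfig()
    na = records["padj"].isna() | records["log2fc"].isna()
    if na.any():
        logger.info("filter_de: dropping %d record(s) with missing values", int(na.sum()))
    rec = records[~na]
    lfc_min = math.log2(cfg.fold_change_min)
    keep = (rec["log2fc"].abs() >= lfc_min) & (rec["padj"] <= cfg.padj_max)
    return rec[keep].reset_index(drop=True)


def overlap_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive membership-pattern counts over named sets (UpSet style).

    Keys are sorted tuples of set names; an element contributes to exactly
    the pattern of sets containing it, so pattern counts sum to |union|.
    Empty patterns are omitted.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for element in set().union(*sets.values()):
        pattern = tuple(n for n in names if element in sets[n])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean) / sd with the population (n-denominator) sd.

    Zero-variance rows become all-zero, with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("row_zscore: %d zero-variance row(s) set to zero", int(flat.sum()))
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def spearman_matrix(cpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Library x library Spearman rank correlation (midranks for ties)."""
    if cpm_matrix.shape[1] < 2 or cpm_matrix.shape[0] < 3:
        raise ValueError("need >= 2 libraries and >= 3 genes")
    rho = stats.spearmanr(cpm_matrix.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-library case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cpm_matrix.columns, columns=cpm_matrix.columns)


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR quantification: 2^-ΔΔCt.

    ΔCt = Ct(target) - Ct(reference) within each condition; ΔΔCt is the
    case ΔCt minus the control ΔCt, and the fold change is 2^-ΔΔCt.
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
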