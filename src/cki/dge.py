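"""Tumor-vs-normal differential overexpression.

Counts are normalized to log2 counts-per-million (CPM), lowly expressed genes
are removed, and each remaining gene is tested with Welch's two-sample t test
on log2-CPM. P values are Benjamini-Hochberg adjusted; a gene earns the
binary overexpression component iff log2FC exceeds the fold-change threshold
(default 1) AND the FDR falls below the threshold (default 0.01).
Under-expressed genes are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix


@dataclass
class DgeResult:
    """Per-gene fold change, raw and adjusted p values, and the binary flag."""

    table: pd.DataFrame  # indexed by gene: log2fc, p_value, fdr, overexpressed_flag

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["overexpressed_flag"]])


def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million on the raw scale."""
    lib = matrix.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero library for sample(s) {list(zero)}")
    return matrix.counts / lib * 1e6


def cpm_normalize(matrix: ExpressionMatrix, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudo); ``pseudo`` keeps zero counts finite."""
    if pseudo <= 0:
        raise ValueError("pseudo offset must be positive")
    return np.log2(cpm(matrix) + pseudo)


def filter_low_expression(matrix: ExpressionMatrix, min_cpm: float = 1.0,
                          min_samples: int | None = None) -> pd.Series:
    """Boolean keep-mask: CPM >= ``min_cpm`` in at least ``min_samples``
    samples. The default ``min_samples`` is the smaller group size, so a gene
    expressed in only one of the two groups can still survive the filter."""
    if min_samples is None:
        min_samples = min(len(matrix.tumor_samples), len(matrix.normal_samples))
        min_samples = max(min_samples, 1)
    keep = (cpm(matrix) >= min_cpm).sum(axis=1) >= min_samples
    return keep.rename("keep")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_overexpression(matrix: ExpressionMatrix,
                                fc_threshold: float = 1.0,
                                fdr_threshold: float = 0.01,
                                pseudo: float = 1.0,
                                genes=None) -> DgeResult:
    """Welch test of tumor vs normal log2-CPM for every (retained) gene.

    Mirrors the cohort inclusion rule: at least three tumor and three normal
    samples are required, otherwise the whole cohort is refused.
    """
    tumor = matrix.tumor_samples
    normal = matrix.normal_samples
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError(
            f"differential expression needs >=3 samples per group "
            f"(got {len(tumor)} tumor, {len(normal)} normal)"
        )
    logcpm = cpm_normalize(matrix, pseudo=pseudo)
    if genes is not None:
        logcpm = logcpm.loc[list(genes)]
    t_arr = logcpm[tumor].to_numpy()
    n_arr = logcpm[normal].to_numpy()
    log2fc = t_arr.mean(axis=1) - n_arr.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(t_arr, n_arr, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    fdr = bh_adjust(p)
    flag = (log2fc > fc_threshold) & (fdr < fdr_threshold)
    return DgeResult(
        pd.DataFrame(
            {"log2fc": log2fc, "p_value": p, "fdr": fdr, "overexpressed_flag": flag},
            index=logcpm.index,
        )
    )
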