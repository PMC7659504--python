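"""Benchmarking CKI scores against loss-of-function dependency screens.

Cell-line dependency scores are dichotomized at the conventional cutoff
(dependent iff score strictly below -1), and the CKI is evaluated as a
predictor of dependency per cell line and at the tissue level (mean
dependency per gene across the tissue's lines): Kruskal-Wallis comparison of
CKI between dependent and non-dependent genes, Spearman rank correlation and
a least-squares linear fit of CKI on dependency, and the ROC area computed
by the rank (Mann-Whitney) formulation with ties counted half.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_formats import DependencyMatrix
from .scoring import GeneScoreCard

logger = logging.getLogger(__name__)

DEPENDENT_CUTOFF = -1.0


def dichotomize_dependency(scores: pd.Series,
                           cutoff: float = DEPENDENT_CUTOFF) -> pd.Series:
    """Dependent iff score < cutoff (strict: exactly -1 is not dependent).
    Genes with missing scores are excluded and counted in ``attrs``."""
    missing = scores.isna()
    out = (scores[~missing] < cutoff).rename("dependent")
    out.attrs["n_missing"] = int(missing.sum())
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from chi-square
    with k-1 degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        return 0.0, 1.0  # identical groups
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho with t-approximation p; (nan, nan) when either
    vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Spearman needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, FPR, TPR): AUC is the probability that a random positive
    out-scores a random negative, ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return float(auc), fpr, tpr


def linear_fit(x, y) -> dict:
    """Ordinary least-squares slope/intercept/R^2 with the slope t-test p."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2), "p_value": float(res.pvalue)}


def _evaluate(cki: pd.Series, dep: pd.Series) -> dict:
    """All benchmark statistics of CKI against one dependency vector."""
    flags = dichotomize_dependency(dep)
    shared = cki.index.intersection(flags.index)
    cki, dep, flags = cki.loc[shared], dep.loc[shared], flags.loc[shared]
    result: dict = {
        "n_genes": int(len(shared)),
        "n_dependent": int(flags.sum()),
        "n_missing_scores": flags.attrs.get("n_missing", 0),
    }
    if flags.sum() == 0 or (~flags).sum() == 0:
        result["skipped"] = "single dependency class"
        return result
    h, p = kruskal_wallis([cki[flags].to_numpy(), cki[~flags].to_numpy()])
    rho, rho_p = spearman_correlation(cki.to_numpy(), dep.to_numpy())
    auc, _, _ = roc_auc(cki.to_numpy(), flags.to_numpy())
    result.update(
        mean_cki_dependent=float(cki[flags].mean()),
        mean_cki_not_dependent=float(cki[~flags].mean()),
        kruskal_h=h, kruskal_p=p,
        spearman_rho=rho, spearman_p=rho_p,
        linear=linear_fit(dep.to_numpy(), cki.to_numpy()),
        auc=auc,
    )
    return result


def benchmark_cohort(cards: Sequence[GeneScoreCard], dependency: DependencyMatrix,
                     cohort_tissue: Mapping[str, str]) -> dict:
    """Benchmark one cohort's scorecards against the dependency matrix.

    The cohort maps to a tissue; every cell line of that tissue is evaluated
    separately, then once more at the tissue level on the per-gene mean
    dependency. Genes absent from the dependency matrix are counted as
    unmatched. Lines with a single dependency class are skipped with a
    reason.
    """
    if not cards:
        raise ValueError("no scorecards to benchmark")
    cohort = cards[0].cohort
    tissue = cohort_tissue.get(cohort)
    if tissue is None:
        raise ValueError(f"no tissue mapping for cohort {cohort!r}")
    lines = dependency.lines_for_tissue(tissue)
    if not lines:
        raise ValueError(f"no cell lines for tissue {tissue!r}")
    cki = pd.Series({c.gene: c.cki_percent for c in cards})
    matched = cki.index.intersection(dependency.scores.index)
    report: dict = {
        "cohort": cohort,
        "tissue": tissue,
        "n_scored_genes": int(len(cki)),
        "n_matched_genes": int(len(matched)),
        "n_unmatched_genes": int(len(cki) - len(matched)),
        "cell_lines": {},
    }
    if len(matched) == 0:
        raise ValueError("no genes shared between scorecards and dependency matrix")
    cki = cki.loc[matched]
    for line in lines:
        report["cell_lines"][line] = _evaluate(cki, dependency.scores.loc[matched, line])
    mean_dep = dependency.scores.loc[matched, lines].mean(axis=1)
    report["tissue_level"] = _evaluate(cki, mean_dep)
    return report
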