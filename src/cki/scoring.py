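"""Assembly of the Clinical Kinase Index (CKI).

The raw score of a gene in a cohort is the sum of three binary evidence
components (significant overexpression, adverse expression-stratified
survival, significant mutational hotspot) and the per-parameter clinical
scores (each in [0, 1]). The CKI percentage divides the raw score by the
maximum attainable in that cohort — 1 per available binary component plus 1
per clinical parameter with sufficient data — and multiplies by 100, so
cohorts with different clinical coverage remain comparable. Ranks use
competition ranking (ties share the minimum rank) with lexicographic gene
order for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneScoreCard:
    """Per-gene evidence components, raw score, maximum, CKI percent, rank."""

    gene: str
    cohort: str
    dge_component: Optional[int]  # None = component unavailable in this cohort
    survival_component: Optional[int]
    hotspot_component: Optional[int]
    clinical_components: dict[str, float]
    raw_score: float = 0.0
    max_score: int = 0
    cki_percent: float = 0.0
    rank: int = 0
    tdl: str = "unknown"
    understudied: bool = False
    moa_target: bool = False


def assemble_scorecard(gene: str, cohort: str,
                       dge: Optional[int], survival: Optional[int],
                       hotspot: Optional[int],
                       clinical: Mapping[str, float],
                       tdl: str = "unknown", understudied: bool = False,
                       moa_target: bool = False) -> GeneScoreCard:
    """Combine validated components into a scorecard.

    ``None`` for a binary component means the cohort could not evaluate it
    (e.g. too few normal samples for differential expression); such a
    component is excluded from both the raw score and the maximum. The
    clinical mapping contains only parameters with sufficient data.
    """
    binaries = {"dge": dge, "survival": survival, "hotspot": hotspot}
    for name, val in binaries.items():
        if val is not None and val not in (0, 1):
            raise ValueError(f"{name} component must be 0, 1 or None; got {val!r}")
    for param, val in clinical.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"clinical score for {param} outside [0, 1]: {val}")
    available_binaries = [v for v in binaries.values() if v is not None]
    raw = float(sum(available_binaries)) + float(sum(clinical.values()))
    max_score = len(available_binaries) + len(clinical)
    if max_score == 0:
        raise ValueError(f"gene {gene}: no scoreable component available")
    return GeneScoreCard(
        gene=gene, cohort=cohort,
        dge_component=dge, survival_component=survival, hotspot_component=hotspot,
        clinical_components=dict(clinical),
        raw_score=raw, max_score=max_score,
        # round at 1e-9 so true rational ties are not split by float noise
        cki_percent=round(100.0 * raw / max_score, 9),
        tdl=tdl, understudied=understudied, moa_target=moa_target,
    )


def rank_cohort(cards: Sequence[GeneScoreCard]) -> list[GeneScoreCard]:
    """Competition-rank cards by descending CKI percent; ties share the
    minimum rank; returns cards sorted by (rank, gene)."""
    seen = set()
    for c in cards:
        if c.gene in seen:
            raise ValueError(f"duplicate scorecard for gene {c.gene}")
        seen.add(c.gene)
    scores = np.array([c.cki_percent for c in cards])
    for c in cards:
        c.rank = int((scores > c.cki_percent).sum()) + 1
    return sorted(cards, key=lambda c: (c.rank, c.gene))


def score_table(cards_by_cohort: Mapping[str, Sequence[GeneScoreCard]]) -> pd.DataFrame:
    """Gene x cohort matrix of CKI percentages (NaN where unscored)."""
    frames = {
        cohort: pd.Series({c.gene: c.cki_percent for c in cards})
        for cohort, cards in cards_by_cohort.items()
    }
    return pd.DataFrame(frames)


def cross_cohort_spearman(table: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of CKI scores between cohorts on
    their shared genes; entries with fewer than ``min_shared`` shared genes
    are missing; the diagonal is 1."""
    cohorts = list(table.columns)
    out = pd.DataFrame(np.nan, index=cohorts, columns=cohorts)
    for i, a in enumerate(cohorts):
        out.loc[a, a] = 1.0
        for b in cohorts[i + 1:]:
            shared = table[[a, b]].dropna()
            if len(shared) < min_shared:
                continue
            rho = stats.spearmanr(shared[a], shared[b]).statistic
            out.loc[a, b] = out.loc[b, a] = float(rho)
    return out


def top_quartile_set(cards: Sequence[GeneScoreCard]) -> set[str]:
    """Genes in the top 25% by CKI percent, boundary ties included."""
    if not cards:
        return set()
    scores = sorted((c.cki_percent for c in cards), reverse=True)
    k = int(np.ceil(0.25 * len(scores)))
    cutoff = scores[k - 1]
    return {c.gene for c in cards if c.cki_percent >= cutoff}


def top_quartile_overlap(cards_a: Sequence[GeneScoreCard],
                         cards_b: Sequence[GeneScoreCard]) -> tuple[int, float]:
    """(shared count, Jaccard index) of the two cohorts' top-25% gene sets."""
    a, b = top_quartile_set(cards_a), top_quartile_set(cards_b)
    union = a | b
    inter = a & b
    return len(inter), (len(inter) / len(union) if union else float("nan"))


def summarize_by_annotation(cards: Sequence[GeneScoreCard],
                            stratum: str = "tdl") -> dict:
    """Group CKI scores by an annotation stratum and test for differences.

    ``stratum``: ``tdl`` | ``understudied`` | ``moa`` | ``kinase_group``
    (kinase_group requires cards carrying a ``kinase_group`` attribute; the
    pipeline attaches one). Strata with fewer than two genes are reported
    descriptively but excluded from the omnibus Kruskal-Wallis test and the
    pairwise two-sided rank-sum tests.
    """
    def key(c: GeneScoreCard) -> str:
        if stratum == "tdl":
            return c.tdl
        if stratum == "understudied":
            return "understudied" if c.understudied else "studied"
        if stratum == "moa":
            return "MOA" if c.moa_target else "non-MOA"
        if stratum == "kinase_group":
            return getattr(c, "kinase_group", "unknown")
        raise ValueError(f"unknown stratum {stratum!r}")

    groups: dict[str, list[float]] = {}
    for c in cards:
        groups.setdefault(key(c), []).append(c.cki_percent)
    descriptives = {
        name: {"n": len(vals), "mean": float(np.mean(vals)),
               "median": float(np.median(vals))}
        for name, vals in groups.items()
    }
    testable = {name: vals for name, vals in groups.items() if len(vals) >= 2}
    report: dict = {"stratum": stratum, "groups": descriptives,
                    "kruskal_p": None, "pairwise": {}}
    if len(testable) >= 2:
        names = sorted(testable)
        samples = [np.asarray(testable[n]) for n in names]
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            report["kruskal_p"] = 1.0  # identical strata
        else:
            report["kruskal_p"] = float(stats.kruskal(*samples).pvalue)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = float(stats.mannwhitneyu(testable[a], testable[b],
                                             alternative="two-sided").pvalue)
                report["pairwise"][f"{a}|{b}"] = p
    return report
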