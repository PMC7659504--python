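"""Residue-level mutation clustering ("hotspot") analysis.

A positional-clustering approach in the oncodriveCLUST family: per gene,
position-affecting mutations (missense, nonsense, insertion, deletion) are
binned by residue; seed residues are those whose count exceeds the binomial
quantile expected under uniform placement over the protein; nearby seeds are
merged into clusters, which are extended through adjacent residues mutated
above the uniform background rate. A gene's clustering score is the fraction
of its mutations captured by clusters (in [0, 1]). Significance is judged
against the cross-gene background of clustering scores (leave-one-out z
score, upper-tail normal p); the binary hotspot component additionally
requires a minimum of 5 mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MutationTable

logger = logging.getLogger(__name__)

#: variant classes that affect an amino-acid position
QUALIFYING_CLASSES = frozenset({"missense", "nonsense", "insertion", "deletion"})


@dataclass
class MutationClusterResult:
    gene: str
    total_mutations: int
    clusters: list[tuple[int, int, int]]  # (start_residue, end_residue, n_mutations)
    clustering_score: float
    z: float = float("nan")
    p_value: float = 1.0
    hotspot_flag: bool = False
    degenerate: bool = False


def positional_counts(mutations: MutationTable, gene: str,
                      protein_length: int) -> dict[int, int]:
    """Residue histogram of qualifying mutations for one gene.

    Silent/other records are excluded; repeated hits at one residue from one
    sample count once per (sample, residue) pair; positions beyond the
    protein length are dropped with a warning.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    recs = mutations.for_gene(gene)
    recs = recs[recs["variant_class"].isin(QUALIFYING_CLASSES)]
    recs = recs[recs["protein_position"].notna()]
    n_over = int((recs["protein_position"] > protein_length).sum())
    if n_over:
        logger.warning("%s: dropped %d mutations beyond protein length %d",
                       gene, n_over, protein_length)
        recs = recs[recs["protein_position"] <= protein_length]
    pairs = recs[["sample", "protein_position"]].drop_duplicates()
    counts = pairs["protein_position"].astype(int).value_counts()
    return {int(r): int(c) for r, c in counts.sort_index().items()}


def detect_clusters(histogram: Mapping[int, int], protein_length: int,
                    total_mutations: int, seed_q: float = 0.01,
                    max_gap: int = 5) -> list[tuple[int, int, int]]:
    """Find mutation clusters from a residue histogram.

    Seed residues exceed the binomial quantile of uniform placement at a
    per-gene false-seed level of ``seed_q``: since every residue of the
    protein is a candidate, the per-residue level is Bonferroni-corrected to
    ``seed_q / protein_length`` (otherwise a chance two-hit residue in a
    moderately mutated gene would seed a cluster in ~L * P(X >= 2) of null
    genes). Seeds within ``max_gap`` residues merge; cluster boundaries
    extend through adjacent residues whose count stays above the uniform
    expectation total/length.
    """
    if total_mutations < 1:
        raise ValueError("need at least one mutation")
    if not histogram:
        return []
    threshold = stats.binom.ppf(1.0 - seed_q / protein_length,
                                total_mutations, 1.0 / protein_length)
    # a single mutation at a residue is never clustering evidence, so the
    # seed threshold is floored at 1 even when the quantile degenerates
    threshold = max(threshold, 1.0)
    seeds = sorted(r for r, c in histogram.items() if c > threshold)
    if not seeds:
        return []
    # merge seeds within max_gap into cluster cores
    cores: list[list[int]] = [[seeds[0], seeds[0]]]
    for s in seeds[1:]:
        if s - cores[-1][1] <= max_gap:
            cores[-1][1] = s
        else:
            cores.append([s, s])
    background = total_mutations / protein_length
    clusters: list[list[int]] = []
    for start, end in cores:
        while start > 1 and histogram.get(start - 1, 0) > background:
            start -= 1
        while end < protein_length and histogram.get(end + 1, 0) > background:
            end += 1
        if clusters and start <= clusters[-1][1]:
            clusters[-1][1] = max(clusters[-1][1], end)
        else:
            clusters.append([start, end])
    return [
        (s, e, sum(c for r, c in histogram.items() if s <= r <= e))
        for s, e in clusters
    ]


def gene_clustering_score(clusters, total_mutations: int) -> float:
    """Fraction of a gene's mutations captured by its clusters."""
    if total_mutations < 1:
        raise ValueError("need at least one mutation")
    return sum(n for _, _, n in clusters) / total_mutations


def hotspot_significance(gene_stats: Mapping[str, tuple[float, int, list]],
                         min_mutations: int = 5, alpha: float = 0.05,
                         background_min_mutations: int = 3,
                         min_background_genes: int = 20
                         ) -> dict[str, MutationClusterResult]:
    """Score each gene's clustering against the cross-gene background.

    ``gene_stats`` maps gene -> (clustering_score, total_mutations, clusters).
    The background is the clustering scores of genes with at least
    ``background_min_mutations`` mutations, excluding the gene under test
    (leave-one-out). Requires at least ``min_background_genes`` genes with a
    mutation to form a background at all.
    """
    n_with_mut = sum(1 for _, tot, _ in gene_stats.values() if tot >= 1)
    if n_with_mut < min_background_genes:
        raise ValueError(
            f"hotspot background needs >= {min_background_genes} mutated genes "
            f"(got {n_with_mut})"
        )
    bg_genes = [g for g, (_, tot, _) in gene_stats.items()
                if tot >= background_min_mutations]
    bg_scores = np.array([gene_stats[g][0] for g in bg_genes], dtype=float)
    bg_index = {g: i for i, g in enumerate(bg_genes)}
    results: dict[str, MutationClusterResult] = {}
    for gene, (score, total, clusters) in gene_stats.items():
        if gene in bg_index:
            loo = np.delete(bg_scores, bg_index[gene])
        else:
            loo = bg_scores
        degenerate = False
        if len(loo) < 2:
            z, p, degenerate = float("nan"), 1.0, True
        else:
            mu = loo.mean()
            sd = loo.std(ddof=1)
            if sd == 0.0:
                # constant background: a score above the common value is
                # infinitely extreme, one equal to it is exactly typical
                degenerate = True
                if score > mu:
                    z, p = float("inf"), 0.0
                elif score == mu:
                    z, p = 0.0, 0.5
                else:
                    z, p = float("-inf"), 1.0
            else:
                z = (score - mu) / sd
                p = float(stats.norm.sf(z))
        flag = bool(p < alpha and total >= min_mutations)
        results[gene] = MutationClusterResult(
            gene=gene, total_mutations=total, clusters=list(clusters),
            clustering_score=score, z=float(z), p_value=float(p),
            hotspot_flag=flag, degenerate=degenerate,
        )
    return results


def analyze_hotspots(mutations: MutationTable,
                     protein_lengths: Mapping[str, Optional[int]],
                     genes=None, seed_q: float = 0.01, max_gap: int = 5,
                     min_mutations: int = 5, alpha: float = 0.05
                     ) -> dict[str, MutationClusterResult]:
    """Full per-cohort hotspot analysis over ``genes`` (default: all mutated
    genes). Protein lengths missing from the catalog fall back to the max
    observed position times 1.1, rounded up."""
    if genes is None:
        genes = sorted(mutations.records["gene"].unique())
    gene_stats: dict[str, tuple[float, int, list]] = {}
    for gene in genes:
        length = protein_lengths.get(gene)
        if length is None:
            observed = mutations.for_gene(gene)["protein_position"].dropna()
            if len(observed) == 0:
                gene_stats[gene] = (0.0, 0, [])
                continue
            length = int(np.ceil(observed.max() * 1.1))
        hist = positional_counts(mutations, gene, int(length))
        total = sum(hist.values())
        if total == 0:
            gene_stats[gene] = (0.0, 0, [])
            continue
        clusters = detect_clusters(hist, int(length), total, seed_q=seed_q,
                                   max_gap=max_gap)
        gene_stats[gene] = (gene_clustering_score(clusters, total), total, clusters)
    return hotspot_significance(gene_stats, min_mutations=min_mutations, alpha=alpha)
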