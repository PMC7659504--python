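"""End-to-end orchestration: cohort bundle -> scorecards -> benchmark.

`score_cohort` applies the cohort eligibility rules (>=3 tumor and >=3
normal samples for differential expression, >=8 patients with expression and
follow-up for survival, a large enough mutated-gene background for hotspots,
per-parameter sufficiency for clinical staging), evaluates every retained
gene, and assembles ranked scorecards; components a cohort cannot evaluate
are excluded from both the raw score and the maximum, so the CKI percentage
stays comparable across cohorts with different data availability.

`run_score` / `run_benchmark` are the file-level entry points behind the
command-line interface: they read a YAML run configuration, write
deterministic TSV/JSON outputs, and embed the seed and resolved-config hash
in every output header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clinical as clinical_mod
from . import depmap as depmap_mod
from . import dge as dge_mod
from . import hotspots as hotspots_mod
from . import survival as survival_mod
from .io_formats import CohortBundle, write_scorecards
from .scoring import (
    GeneScoreCard,
    assemble_scorecard,
    cross_cohort_spearman,
    rank_cohort,
    score_table,
    summarize_by_annotation,
)
from .synthetic_cohort import SimulationConfig, export_bundle, load_bundle, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class ScoreSettings:
    """All tunable module parameters with the pipeline defaults."""

    dge_fc_threshold: float = 1.0
    dge_fdr_threshold: float = 0.01
    dge_min_cpm: float = 1.0
    dge_pseudo: float = 1.0
    survival_alpha: float = 0.05
    survival_q_low: float = 0.25
    survival_q_high: float = 0.75
    clinical_alpha: float = 0.05
    clinical_pairs: str = "all"  # all | consecutive
    clinical_rule: str = "average"  # average | any
    hotspot_seed_q: float = 0.01
    hotspot_max_gap: int = 5
    hotspot_min_mutations: int = 5
    hotspot_alpha: float = 0.05

    @classmethod
    def from_mapping(cls, cfg: dict) -> "ScoreSettings":
        kwargs = {}
        for section in ("dge", "survival", "clinical", "hotspot"):
            for key, val in (cfg.get(section) or {}).items():
                name = f"{section}_{key}"
                if not hasattr(cls, name) and name not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {section}.{key}")
                kwargs[name] = val
        return cls(**kwargs)


def score_cohort(bundle: CohortBundle,
                 settings: ScoreSettings | None = None) -> tuple[list[GeneScoreCard], dict]:
    """Score every retained gene of a cohort; returns (ranked cards, summary).

    The summary records every cohort-level exclusion/availability decision:
    filtered genes, whether each binary component could be evaluated, which
    clinical parameters had sufficient data, and patient exclusion counts.
    """
    settings = settings or ScoreSettings()
    em = bundle.expression
    summary: dict = {"cohort": bundle.cohort, "n_genes_input": len(em.gene_ids),
                     "n_tumor": len(em.tumor_samples),
                     "n_normal": len(em.normal_samples)}

    keep = dge_mod.filter_low_expression(em, min_cpm=settings.dge_min_cpm)
    retained = list(keep.index[keep])
    summary["n_genes_filtered_low_expression"] = int((~keep).sum())
    summary["n_genes_scored"] = len(retained)
    if not retained:
        raise ValueError("no genes survive the low-expression filter")

    # differential overexpression (cohort eligibility: >=3 per group)
    dge_available = len(em.tumor_samples) >= 3 and len(em.normal_samples) >= 3
    summary["dge_available"] = dge_available
    dge_flags: dict[str, Optional[int]] = {}
    if dge_available:
        res = dge_mod.differential_overexpression(
            em, fc_threshold=settings.dge_fc_threshold,
            fdr_threshold=settings.dge_fdr_threshold,
            pseudo=settings.dge_pseudo, genes=retained)
        dge_flags = {g: int(f) for g, f in res.table["overexpressed_flag"].items()}
        summary["n_dge_flagged"] = int(res.table["overexpressed_flag"].sum())
    else:
        logger.warning("cohort %s: <3 samples in a group, differential expression "
                       "unavailable; maximum score reduced", bundle.cohort)

    # per-patient tumor expression (first tumor sample per patient)
    logcpm = dge_mod.cpm_normalize(em, pseudo=settings.dge_pseudo)
    tumor_meta = pd.DataFrame({
        "sample": em.tumor_samples,
        "patient": [em.patient_id[s] for s in em.tumor_samples],
    }).drop_duplicates(subset="patient", keep="first")
    patient_expr = logcpm.loc[retained, tumor_meta["sample"]]
    patient_expr.columns = tumor_meta["patient"].values

    # survival
    records = survival_mod.build_survival_records(bundle.clinical)
    summary["n_survival_patients"] = len(records)
    summary["n_survival_excluded"] = records.attrs.get("n_excluded", 0)
    usable_records = records[records["patient_id"].isin(patient_expr.columns)]
    survival_available = len(usable_records) >= 8
    summary["survival_available"] = survival_available

    # clinical staging
    assignments = clinical_mod.stage_assignments(bundle.clinical)
    assignments = assignments.loc[assignments.index.intersection(patient_expr.columns)]
    params_available = clinical_mod.available_parameters(assignments)
    summary["clinical_parameters_available"] = params_available
    clin_matrix = clinical_mod.clinical_scores_matrix(
        patient_expr, assignments, parameters=params_available,
        alpha=settings.clinical_alpha, pairs=settings.clinical_pairs,
        rule=settings.clinical_rule)

    # mutation hotspots
    hotspot_results: dict = {}
    hotspot_available = False
    if len(bundle.mutations):
        lengths = {g: bundle.annotations.protein_length(g) for g in retained}
        try:
            hotspot_results = hotspots_mod.analyze_hotspots(
                bundle.mutations, lengths, genes=retained,
                seed_q=settings.hotspot_seed_q, max_gap=settings.hotspot_max_gap,
                min_mutations=settings.hotspot_min_mutations,
                alpha=settings.hotspot_alpha)
            hotspot_available = True
        except ValueError as exc:
            logger.warning("cohort %s: hotspot analysis unavailable (%s)",
                           bundle.cohort, exc)
    else:
        logger.warning("cohort %s: no mutation data; hotspot component unavailable",
                       bundle.cohort)
    summary["hotspot_available"] = hotspot_available
    if hotspot_available:
        summary["n_hotspot_flagged"] = sum(
            r.hotspot_flag for r in hotspot_results.values())

    cards = []
    for gene in retained:
        expr = patient_expr.loc[gene]
        surv_component: Optional[int] = None
        if survival_available:
            surv_component, _ = survival_mod.survival_score(
                expr, usable_records, alpha=settings.survival_alpha,
                q_low=settings.survival_q_low, q_high=settings.survival_q_high)
        clin_components = {p: float(clin_matrix.at[gene, p])
                           for p in clin_matrix.columns}
        hot_component: Optional[int] = None
        if hotspot_available:
            res = hotspot_results.get(gene)
            hot_component = int(res.hotspot_flag) if res is not None else 0
        card = assemble_scorecard(
            gene=gene, cohort=bundle.cohort,
            dge=dge_flags.get(gene) if dge_available else None,
            survival=surv_component, hotspot=hot_component,
            clinical=clin_components,
            tdl=bundle.annotations.tdl(gene),
            understudied=bundle.annotations.understudied(gene),
            moa_target=bundle.annotations.moa_target(gene, bundle.cohort),
        )
        card.kinase_group = bundle.annotations.kinase_group(gene)
        cards.append(card)
    return rank_cohort(cards), summary


# ---------------------------------------------------------------------------
# file-level runs
# ---------------------------------------------------------------------------


def load_run_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "cohorts" not in cfg or not cfg["cohorts"]:
        raise ValueError("run config must define at least one cohort")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_bundle(name: str, spec: dict, seed: int) -> CohortBundle:
    if "bundle" in spec:
        return load_bundle(spec["bundle"])
    if "simulate" in spec:
        sim_kwargs = dict(spec["simulate"] or {})
        sim_kwargs.setdefault("cohort", name)
        sim_kwargs.setdefault("seed", seed)
        if "protein_length_range" in sim_kwargs:
            sim_kwargs["protein_length_range"] = tuple(sim_kwargs["protein_length_range"])
        bundle, _ = simulate_cohort(SimulationConfig(**sim_kwargs))
        return bundle
    raise ValueError(f"cohort {name!r}: need a 'bundle' path or a 'simulate' block")


def run_score(cfg: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Score every configured cohort and write scorecards, rank lists, the
    cross-cohort correlation matrix and a run summary under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    settings = ScoreSettings.from_mapping(cfg)
    header = {"seed": seed, "config_hash": _config_hash(cfg)}

    cards_by_cohort: dict[str, list[GeneScoreCard]] = {}
    summaries: dict[str, dict] = {}
    for name, spec in cfg["cohorts"].items():
        bundle = _resolve_bundle(name, spec or {}, seed)
        cards, summary = score_cohort(bundle, settings)
        cards_by_cohort[name] = cards
        summaries[name] = summary
        write_scorecards(cards, out_dir / f"scorecards_{name}.tsv",
                         out_dir / f"summary_{name}.json", header=header)
    if len(cards_by_cohort) > 1:
        corr = cross_cohort_spearman(score_table(cards_by_cohort))
        with open(out_dir / "cross_cohort_spearman.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            for key, val in header.items():
                fh.write(f"# {key}={val}\n")
            corr.to_csv(fh, sep="\t", lineterminator="\n")
    run_summary = {"run": {k: str(v) for k, v in header.items()},
                   "cohorts": summaries}
    with open(out_dir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"cards": cards_by_cohort, "summaries": summaries, "header": header}


def run_benchmark(cfg: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Score cohorts, then benchmark each against its dependency matrix.

    Requires each benchmarked cohort's bundle to carry a dependency matrix,
    and a ``benchmark.tissue_map`` (cohort -> tissue) in the config; for
    simulated cohorts the tissue defaults to the simulated one.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    settings = ScoreSettings.from_mapping(cfg)
    header = {"seed": seed, "config_hash": _config_hash(cfg)}
    tissue_map = dict((cfg.get("benchmark") or {}).get("tissue_map") or {})

    reports: dict[str, dict] = {}
    for name, spec in cfg["cohorts"].items():
        bundle = _resolve_bundle(name, spec or {}, seed)
        if bundle.dependency is None:
            logger.warning("cohort %s: no dependency matrix, benchmark skipped", name)
            continue
        if name not in tissue_map:
            tissues = bundle.dependency.cell_line_tissue.unique()
            if len(tissues) == 1:
                tissue_map[name] = str(tissues[0])
        cards, _ = score_cohort(bundle, settings)
        reports[name] = depmap_mod.benchmark_cohort(cards, bundle.dependency,
                                                    tissue_map)
    if not reports:
        raise ValueError("no cohort had a dependency matrix to benchmark; "
                         "run the scoring step with dependency data first")
    payload = {"run": {k: str(v) for k, v in header.items()}, "reports": reports}
    with open(out_dir / "benchmark_report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
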