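"""Synthetic cohort generator with planted, recoverable effects.

Emulates the statistical structure the Clinical Kinase Index assumes about a
tumor cohort:

* negative-binomial RNA-seq counts with log-normal library sizes and a
  planted tumor/normal log2 fold change for a chosen gene fraction;
* censored survival times from an exponential proportional-hazards model in
  which a latent high-risk quartile of patients carries an elevated hazard,
  and planted "prognostic" genes are overexpressed in exactly that risk
  stratum (so each planted gene's upper expression quartile is the bad arm);
* ordinal T/N/M/grade/stage labels, with planted genes whose log-expression
  rises linearly with T level;
* residue-level somatic mutations placed uniformly over the protein, except
  planted hotspot genes which concentrate a fixed fraction at one residue;
* a dependency-score matrix with planted "dependent" genes centered below
  the conventional -1 cutoff.

Every planted effect is recorded in a :class:`TruthManifest` so that
parameter-recovery tests can compare pipeline calls against ground truth.
One seed sequence is split into named substreams (library/counts/survival/
stages/mutations/dependency/annotations/planting) so the components are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationCatalog,
    ClinicalTable,
    CohortBundle,
    DependencyMatrix,
    ExpressionMatrix,
    MutationTable,
    NORMAL_CODE,
    TUMOR_CODE,
    read_annotations,
    read_clinical,
    read_dependency,
    read_expression,
    read_maf,
    write_annotations,
    write_clinical,
    write_dependency,
    write_expression,
    write_maf,
)

_SUBSTREAMS = (
    "planting",
    "library",
    "counts",
    "survival",
    "stages",
    "mutations",
    "dependency",
    "annotations",
)

_ROMAN = {1: "i", 2: "ii", 3: "iii", 4: "iv"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized solid-tumor cohort: moderate sequencing
    depth (NB mean 100, dispersion 0.2), ~30% censoring, a 3-fold hazard for
    the high-risk stratum, a 0.5 log2-unit per-T-level expression trend and
    hotspot genes concentrating 60% of their mutations at one residue.
    """

    n_genes: int = 200
    n_tumor: int = 100
    n_normal: int = 50
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    library_sigma: float = 0.3  # log-normal sd of library-size factors

    frac_dge: float = 0.0
    frac_surv: float = 0.0
    frac_clinical: float = 0.0
    frac_hotspot: float = 0.0
    frac_dependent: float = 0.0
    #: if set, one common gene set (this fraction of genes) carries all five
    #: planted effects; the per-effect fractions are ignored
    composite_fraction: Optional[float] = None

    planted_log2fc: float = 2.0
    hazard_ratio_high: float = 3.0
    surv_expr_log2_shift: float = 1.5  # overexpression of prognostic genes in the risk stratum
    risk_fraction: float = 0.25
    base_death_rate: float = 1.0 / 500.0  # events per day
    censor_rate: float = 0.3

    stage_levels: int = 4
    stage_shift: float = 0.5  # log2 units per T level

    gene_mut_rate: float = 10.0
    hotspot_concentration: float = 0.6
    protein_length_range: tuple[int, int] = (300, 800)

    dep_mean_null: float = 0.0
    dep_mean_dependent: float = -1.5
    dep_sd: float = 0.3
    n_cell_lines: int = 4
    tissue: str = "lung"

    cohort: str = "SIM"
    seed: int = 0
    #: when set, the planted-gene draw uses this seed instead of ``seed``,
    #: so cohorts simulated with different seeds can share planted genes
    planting_seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_tumor < 1 or self.n_normal < 0:
            raise ValueError("need at least one tumor sample")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.hazard_ratio_high < 1:
            raise ValueError("hazard_ratio_high must be >= 1")
        fracs = [self.frac_dge, self.frac_surv, self.frac_clinical,
                 self.frac_hotspot, self.frac_dependent]
        if self.composite_fraction is not None:
            fracs.append(self.composite_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length_range")


@dataclass
class TruthManifest:
    """Per-gene planted-effect flags (and the hotspot residue when planted)."""

    table: pd.DataFrame  # indexed by gene; bool columns + hotspot_residue

    FLAGS = ("planted_dge", "planted_surv", "planted_clinical",
             "planted_hotspot", "planted_dependent")

    def planted(self, flag: str) -> list[str]:
        return list(self.table.index[self.table[flag]])

    def composite(self) -> pd.Series:
        """True where a gene carries every planted effect."""
        out = pd.Series(True, index=self.table.index)
        for flag in self.FLAGS:
            out &= self.table[flag]
        return out

    def equals(self, other: "TruthManifest") -> bool:
        return self.table.equals(other.table)


def _rngs(seed: int, planting_seed: Optional[int] = None) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    rngs = {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}
    if planting_seed is not None:
        rngs["planting"] = np.random.default_rng(
            np.random.SeedSequence(planting_seed).spawn(1)[0]
        )
    return rngs


def _plant(rng: np.random.Generator, genes: list[str], frac: float) -> pd.Series:
    flags = pd.Series(False, index=genes)
    k = int(round(frac * len(genes)))
    if k:
        chosen = rng.choice(len(genes), size=k, replace=False)
        flags.iloc[np.sort(chosen)] = True
    return flags


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, TruthManifest]:
    """Generate a full :class:`CohortBundle` plus its :class:`TruthManifest`.

    The same config (including seed) always produces bit-identical output.
    """
    config.validate()
    rng = _rngs(config.seed, config.planting_seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    patients = [f"P{i:04d}" for i in range(1, config.n_tumor + 1)]
    tumor_samples = [f"{p}-{TUMOR_CODE}" for p in patients]
    normal_samples = [f"P{i:04d}-{NORMAL_CODE}" for i in range(1, config.n_normal + 1)]

    # --- planted-effect bookkeeping -------------------------------------
    if config.composite_fraction is not None:
        common = _plant(rng["planting"], genes, config.composite_fraction)
        flags = {f: common.copy() for f in TruthManifest.FLAGS}
    else:
        flags = {
            "planted_dge": _plant(rng["planting"], genes, config.frac_dge),
            "planted_surv": _plant(rng["planting"], genes, config.frac_surv),
            "planted_clinical": _plant(rng["planting"], genes, config.frac_clinical),
            "planted_hotspot": _plant(rng["planting"], genes, config.frac_hotspot),
            "planted_dependent": _plant(rng["planting"], genes, config.frac_dependent),
        }

    # --- patient-level latent structure ----------------------------------
    n_risk = int(round(config.risk_fraction * config.n_tumor))
    risk_idx = np.sort(rng["survival"].choice(config.n_tumor, size=n_risk, replace=False))
    risk = np.zeros(config.n_tumor, dtype=bool)
    risk[risk_idx] = True

    srng = rng["stages"]
    t_level = srng.integers(1, config.stage_levels + 1, size=config.n_tumor)
    n_level = srng.integers(0, 4, size=config.n_tumor)
    m_level = (srng.random(config.n_tumor) < 0.2).astype(int)
    grade = srng.integers(1, 5, size=config.n_tumor)
    path_stage = srng.integers(1, 5, size=config.n_tumor)
    clin_stage = srng.integers(1, 5, size=config.n_tumor)

    # --- counts -----------------------------------------------------------
    all_samples = tumor_samples + normal_samples
    lib = np.exp(rng["library"].normal(0.0, config.library_sigma, size=len(all_samples)))

    log2_effect = np.zeros((config.n_genes, len(all_samples)))
    n_t = config.n_tumor
    dge_rows = flags["planted_dge"].to_numpy()
    log2_effect[np.ix_(dge_rows, np.arange(n_t))] += config.planted_log2fc
    surv_rows = flags["planted_surv"].to_numpy()
    log2_effect[np.ix_(surv_rows, np.flatnonzero(risk))] += config.surv_expr_log2_shift
    clin_rows = flags["planted_clinical"].to_numpy()
    log2_effect[np.ix_(clin_rows, np.arange(n_t))] += config.stage_shift * (t_level - 1)

    mean = config.baseline_mean * lib[None, :] * np.exp2(log2_effect)
    r = 1.0 / config.dispersion
    p = r / (r + mean)
    counts = rng["counts"].negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=all_samples, dtype=np.int64)

    expression = ExpressionMatrix(
        counts=counts_df,
        sample_type=pd.Series(
            [TUMOR_CODE] * n_t + [NORMAL_CODE] * config.n_normal,
            index=all_samples, name="sample_type",
        ),
        patient_id=pd.Series(
            patients + [s.rsplit("-", 1)[0] for s in normal_samples],
            index=all_samples, name="patient_id",
        ),
    )

    # --- survival ----------------------------------------------------------
    vrng = rng["survival"]
    hazard = config.base_death_rate * np.where(risk, config.hazard_ratio_high, 1.0)
    event_time = vrng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_rate = config.base_death_rate * config.censor_rate / (1 - config.censor_rate)
        censor_time = vrng.exponential(1.0 / censor_rate, size=config.n_tumor)
    else:
        censor_time = np.full(config.n_tumor, np.inf)
    observed = np.minimum(event_time, censor_time)
    dead = event_time <= censor_time
    days = np.maximum(1, np.round(observed)).astype(int)

    suffix = ["", "a", "b"]
    clinical_df = pd.DataFrame(
        {
            "patient_id": patients,
            "vital_status": np.where(dead, "dead", "alive"),
            "days_to_death": np.where(dead, days.astype(float), np.nan),
            "days_to_last_follow_up": np.where(dead, np.nan, days.astype(float)),
            "t_stage": [f"t{l}{srng.choice(suffix)}" for l in t_level],
            "n_stage": [f"n{l}{srng.choice(suffix)}" for l in n_level],
            "m_stage": [f"m{l}" for l in m_level],
            "grade": [f"g{l}" for l in grade],
            "pathologic_stage": [f"stage {_ROMAN[l]}{srng.choice(suffix)}" for l in path_stage],
            "clinical_stage": [f"stage {_ROMAN[l]}{srng.choice(suffix)}" for l in clin_stage],
        }
    )
    clinical = ClinicalTable(clinical_df)

    # --- mutations ----------------------------------------------------------
    mrng = rng["mutations"]
    lo, hi = config.protein_length_range
    protein_length = mrng.integers(lo, hi + 1, size=config.n_genes)
    hotspot_residue = np.full(config.n_genes, -1)
    classes = np.array(["missense", "nonsense", "insertion", "deletion", "silent"])
    class_p = np.array([0.70, 0.10, 0.05, 0.05, 0.10])
    rows: list[tuple[str, int, str, str]] = []
    for gi, gene in enumerate(genes):
        n_mut = int(mrng.poisson(config.gene_mut_rate))
        if n_mut == 0:
            continue
        length = int(protein_length[gi])
        positions = mrng.integers(1, length + 1, size=n_mut)
        vclasses = mrng.choice(classes, size=n_mut, p=class_p)
        if flags["planted_hotspot"].iloc[gi]:
            residue = int(mrng.integers(1, length + 1))
            hotspot_residue[gi] = residue
            n_hot = int(round(config.hotspot_concentration * n_mut))
            positions[:n_hot] = residue
            vclasses[:n_hot] = "missense"  # hotspot mutations must be position-affecting
        barcodes = mrng.choice(tumor_samples, size=n_mut)
        rows.extend(zip([gene] * n_mut, positions.tolist(), vclasses.tolist(),
                        barcodes.tolist()))
    mutations = MutationTable(
        pd.DataFrame(rows, columns=["gene", "protein_position", "variant_class", "sample"])
        if rows
        else pd.DataFrame(
            {"gene": pd.Series(dtype=str),
             "protein_position": pd.Series(dtype="Int64"),
             "variant_class": pd.Series(dtype=str),
             "sample": pd.Series(dtype=str)}
        )
    )

    # --- dependency ----------------------------------------------------------
    drng = rng["dependency"]
    cell_lines = [f"{config.tissue.upper()}-CL{i}" for i in range(1, config.n_cell_lines + 1)]
    dep_mean = np.where(flags["planted_dependent"].to_numpy(),
                        config.dep_mean_dependent, config.dep_mean_null)
    dep = drng.normal(dep_mean[:, None], config.dep_sd,
                      size=(config.n_genes, config.n_cell_lines))
    dependency = DependencyMatrix(
        scores=pd.DataFrame(dep, index=pd.Index(genes, name="gene"), columns=cell_lines),
        cell_line_tissue=pd.Series(config.tissue, index=pd.Index(cell_lines, name="cell_line"),
                                   name="tissue"),
    )

    # --- annotations ----------------------------------------------------------
    arng = rng["annotations"]
    tdl = arng.choice(["Tclin", "Tchem", "Tbio", "Tdark"], size=config.n_genes,
                      p=[0.08, 0.30, 0.45, 0.17])
    groups = arng.choice(["TK", "TKL", "CMGC", "CAMK", "AGC", "CK1", "STE", "Other",
                          "Atypical"], size=config.n_genes)
    moa = flags["planted_dge"].to_numpy() & flags["planted_surv"].to_numpy()
    understudied = np.where(
        tdl == "Tclin", False, arng.random(config.n_genes) < 0.35
    ) & ~moa
    in_trial = (np.isin(tdl, ["Tclin", "Tchem"])) & (arng.random(config.n_genes) < 0.3)
    ann_df = pd.DataFrame(
        {
            "gene": genes,
            "tdl": tdl,
            "understudied": understudied.astype(bool),
            "kinase_group": groups,
            "kinase_family": [f"{g}-fam{arng.integers(1, 4)}" for g in groups],
            "moa_target_cancers": [config.cohort if m else "" for m in moa],
            "in_trial_cancers": [config.cohort if t else "" for t in in_trial],
            "protein_length": pd.array(protein_length, dtype="Int64"),
        }
    )
    annotations = AnnotationCatalog(ann_df.set_index("gene"))

    manifest = TruthManifest(
        pd.DataFrame(
            {
                **{name: flags[name] for name in TruthManifest.FLAGS},
                "hotspot_residue": pd.array(
                    [r if r > 0 else pd.NA for r in hotspot_residue], dtype="Int64"
                ),
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    bundle = CohortBundle(
        cohort=config.cohort,
        expression=expression,
        clinical=clinical,
        mutations=mutations,
        annotations=annotations,
        dependency=dependency,
    )
    return bundle, manifest


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "clinical": "clinical.tsv",
    "mutations": "mutations.maf",
    "annotations": "annotations.tsv",
    "dependency": "dependency.tsv",
    "cell_lines": "cell_lines.tsv",
    "manifest": "truth_manifest.tsv",
}


def export_bundle(bundle: CohortBundle, manifest: Optional[TruthManifest],
                  directory) -> Path:
    """Write every bundle component (and the truth manifest, if given) as TSV
    files under ``directory`` using the :mod:`cki.io_formats` formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, directory / BUNDLE_FILES["counts"],
                     directory / BUNDLE_FILES["samples"])
    write_clinical(bundle.clinical, directory / BUNDLE_FILES["clinical"])
    write_maf(bundle.mutations, directory / BUNDLE_FILES["mutations"])
    write_annotations(bundle.annotations, directory / BUNDLE_FILES["annotations"])
    if bundle.dependency is not None:
        write_dependency(bundle.dependency, directory / BUNDLE_FILES["dependency"],
                         directory / BUNDLE_FILES["cell_lines"])
    if manifest is not None:
        out = manifest.table.reset_index().copy()
        for flag in TruthManifest.FLAGS:
            out[flag] = out[flag].map(lambda b: "true" if b else "false")
        out["hotspot_residue"] = out["hotspot_residue"].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
        out.to_csv(directory / BUNDLE_FILES["manifest"], sep="\t", index=False,
                   lineterminator="\n")
    with open(directory / "cohort.txt", "w", encoding="utf-8") as fh:
        fh.write(bundle.cohort + "\n")
    return directory


def load_bundle(directory) -> CohortBundle:
    """Re-read a directory written by :func:`export_bundle`."""
    directory = Path(directory)
    cohort_file = directory / "cohort.txt"
    cohort = cohort_file.read_text(encoding="utf-8").strip() if cohort_file.exists() else directory.name
    dep_path = directory / BUNDLE_FILES["dependency"]
    dependency = (
        read_dependency(dep_path, directory / BUNDLE_FILES["cell_lines"])
        if dep_path.exists()
        else None
    )
    return CohortBundle(
        cohort=cohort,
        expression=read_expression(directory / BUNDLE_FILES["counts"],
                                   directory / BUNDLE_FILES["samples"]),
        clinical=read_clinical(directory / BUNDLE_FILES["clinical"]),
        mutations=read_maf(directory / BUNDLE_FILES["mutations"]),
        annotations=read_annotations(directory / BUNDLE_FILES["annotations"]),
        dependency=dependency,
    )


def load_manifest(directory) -> TruthManifest:
    df = pd.read_csv(Path(directory) / BUNDLE_FILES["manifest"], sep="\t", dtype=str)
    for flag in TruthManifest.FLAGS:
        df[flag] = df[flag] == "true"
    df["hotspot_residue"] = pd.to_numeric(df["hotspot_residue"], errors="coerce").astype(
        "Int64"
    )
    return TruthManifest(df.set_index("gene"))
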