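"""Typed readers and writers for all tabular inputs of the CKI pipeline.

Every downstream module consumes the validated in-memory containers defined
here (:class:`ExpressionMatrix`, :class:`ClinicalTable`, :class:`MutationTable`,
:class:`AnnotationCatalog`, :class:`DependencyMatrix`) — never raw files.
All on-disk formats are plain UTF-8 TSV with "." decimals and LF line
endings; reading a written object reproduces it field for field.

Readers never silently drop rows: every exclusion (duplicate barcode,
unparseable position, out-of-vocabulary label) is counted and logged.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR_CODE = "01"
NORMAL_CODE = "11"

#: canonical variant classes used by the hotspot analysis
VARIANT_CLASSES = ("missense", "nonsense", "insertion", "deletion", "silent", "other")

#: standard MAF column names accepted by :func:`read_maf`
MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "position": "Protein_position",
    "variant_class": "Variant_Classification",
    "sample": "Tumor_Sample_Barcode",
}

#: minimal TSV dialect accepted by :func:`read_maf`
MAF_MINIMAL_COLUMNS = {
    "gene": "gene",
    "position": "protein_position",
    "variant_class": "variant_class",
    "sample": "sample",
}

_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "other",
    "in_frame_ins": "insertion",
    "frame_shift_ins": "insertion",
    "insertion": "insertion",
    "in_frame_del": "deletion",
    "frame_shift_del": "deletion",
    "deletion": "deletion",
    "silent": "silent",
    "synonymous": "silent",
}

TDL_CLASSES = ("Tclin", "Tchem", "Tbio", "Tdark", "unknown")


class FormatError(ValueError):
    """A file violated the documented schema or an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Raw gene x sample count matrix with per-sample metadata.

    ``counts`` is genes x samples with unique gene symbols as the index and
    unique sample barcodes as columns; ``sample_type`` and ``patient_id`` are
    Series indexed by sample barcode. Sample-type codes follow the consortium
    convention: primary tumor ``"01"``, solid-tissue normal ``"11"``.
    """

    counts: pd.DataFrame
    sample_type: pd.Series
    patient_id: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample barcode: {dup!r}")
        if not self.sample_type.index.equals(self.counts.columns):
            raise FormatError("sample_type index does not match count columns")
        if not self.patient_id.index.equals(self.counts.columns):
            raise FormatError("patient_id index does not match count columns")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(self.counts)
            raise FormatError(f"non-numeric count at gene {bad[0]!r}, sample {bad[1]!r}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count {arr[g, s]} at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(arr != np.round(arr))[0]
            raise FormatError(
                f"non-integral count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        unknown = set(self.sample_type.unique()) - {TUMOR_CODE, NORMAL_CODE}
        if unknown:
            raise FormatError(f"unknown sample_type codes: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.sample_type.index[self.sample_type == TUMOR_CODE])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_type.index[self.sample_type == NORMAL_CODE])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.sample_type.equals(other.sample_type)
            and self.patient_id.equals(other.patient_id)
        )


CLINICAL_COLUMNS = [
    "patient_id",
    "vital_status",
    "days_to_death",
    "days_to_last_follow_up",
    "t_stage",
    "n_stage",
    "m_stage",
    "grade",
    "pathologic_stage",
    "clinical_stage",
]


@dataclass
class ClinicalTable:
    """Per-patient clinical record; one row per patient, missing values as NA."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if self.table["patient_id"].duplicated().any():
            dup = self.table["patient_id"][self.table["patient_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate patient_id: {dup!r}")
        for col in ("days_to_death", "days_to_last_follow_up"):
            vals = self.table[col].dropna()
            if (vals < 0).any():
                raise FormatError(f"negative {col}")
        bad = set(self.table["vital_status"].dropna()) - {"alive", "dead"}
        if bad:
            raise FormatError(f"unknown vital_status values: {sorted(bad)}")

    def equals(self, other: "ClinicalTable") -> bool:
        return self.table.reset_index(drop=True).equals(other.table.reset_index(drop=True))


MUTATION_COLUMNS = ["gene", "protein_position", "variant_class", "sample"]


@dataclass
class MutationTable:
    """MAF-derived somatic mutation records.

    ``protein_position`` is a 1-based residue index (nullable integer);
    records with a missing position are retained but unusable for clustering.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        pos = self.records["protein_position"]
        if not isinstance(pos.dtype, pd.Int64Dtype):
            self.records["protein_position"] = pos.astype("Int64")
        known = set(self.records["protein_position"].dropna())
        if known and min(known) < 1:
            raise FormatError("protein_position must be >= 1")
        bad = set(self.records["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise FormatError(f"unknown variant classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.records[self.records["gene"] == gene]

    def equals(self, other: "MutationTable") -> bool:
        return self.records.reset_index(drop=True).equals(
            other.records.reset_index(drop=True)
        )


ANNOTATION_COLUMNS = [
    "gene",
    "tdl",
    "understudied",
    "kinase_group",
    "kinase_family",
    "moa_target_cancers",
    "in_trial_cancers",
    "protein_length",
]


@dataclass
class AnnotationCatalog:
    """Static per-gene target annotations (TDL class, IDG understudied flag,
    kinase phylogeny, cancer-specific MOA-target and trial flags, protein
    length in residues)."""

    table: pd.DataFrame  # indexed by gene

    def __post_init__(self) -> None:
        if self.table.index.name != "gene":
            if "gene" in self.table.columns:
                self.table = self.table.set_index("gene")
            else:
                raise FormatError("annotation table needs a 'gene' column")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate gene in annotation catalog")
        bad = set(self.table["tdl"].dropna()) - set(TDL_CLASSES)
        if bad:
            raise FormatError(f"unknown TDL classes: {sorted(bad)}")

    def tdl(self, gene: str) -> str:
        if gene in self.table.index:
            val = self.table.at[gene, "tdl"]
            if pd.notna(val):
                return str(val)
        return "unknown"

    def understudied(self, gene: str) -> bool:
        if gene in self.table.index:
            return bool(self.table.at[gene, "understudied"])
        return False

    def kinase_group(self, gene: str) -> str:
        if gene in self.table.index:
            val = self.table.at[gene, "kinase_group"]
            if pd.notna(val):
                return str(val)
        return "unknown"

    def moa_target(self, gene: str, cohort: str) -> bool:
        if gene not in self.table.index:
            return False
        cancers = self.table.at[gene, "moa_target_cancers"]
        return cohort in _as_set(cancers)

    def protein_length(self, gene: str) -> Optional[int]:
        if gene in self.table.index:
            val = self.table.at[gene, "protein_length"]
            if pd.notna(val):
                return int(val)
        return None

    def equals(self, other: "AnnotationCatalog") -> bool:
        return self.table.equals(other.table)


@dataclass
class DependencyMatrix:
    """Gene x cell-line loss-of-function dependency scores with a
    cell-line -> tissue mapping. More negative = more essential; scores
    below -1 are conventionally called "dependent"."""

    scores: pd.DataFrame  # genes x cell lines
    cell_line_tissue: pd.Series  # indexed by cell line

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise FormatError("duplicate gene in dependency matrix")
        unmapped = [c for c in self.scores.columns if c not in self.cell_line_tissue.index]
        if unmapped:
            logger.warning("dependency matrix: %d unmapped cell lines", len(unmapped))
        arr = self.scores.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise FormatError("non-finite dependency score")

    def lines_for_tissue(self, tissue: str) -> list[str]:
        lines = self.cell_line_tissue.index[self.cell_line_tissue == tissue]
        return [c for c in lines if c in self.scores.columns]

    def equals(self, other: "DependencyMatrix") -> bool:
        return self.scores.equals(other.scores) and self.cell_line_tissue.equals(
            other.cell_line_tissue
        )


@dataclass
class CohortBundle:
    """All raw inputs for one cancer cohort."""

    cohort: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    annotations: AnnotationCatalog
    dependency: Optional[DependencyMatrix] = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return "?", "?"


def _as_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    text = str(value).strip()
    if not text:
        return set()
    return {tok for tok in (t.strip() for t in text.split(",")) if tok}


def _set_to_field(value) -> str:
    return ",".join(sorted(_as_set(value)))


def parse_protein_position(text) -> Optional[int]:
    """Parse a MAF ``Protein_position`` field to a 1-based residue index.

    Accepts plain integers, the position/length dialect (``"600/766"`` -> 600)
    and ranges (``"600-602/766"`` -> 600). Missing markers (``"-"``, ``"."``,
    empty) give ``None``.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if s in ("", "-", ".", "?", "NA"):
        return None
    m = re.match(r"^(\d+)", s)
    if not m:
        return None
    pos = int(m.group(1))
    return pos if pos >= 1 else None


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what}: missing mandatory column(s) {missing}; expected header with "
            f"{list(cols)}"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(counts_path, samples_path) -> ExpressionMatrix:
    """Read a counts TSV (first column gene symbol, header row of sample
    barcodes) and its sample-metadata sidecar (sample_id, patient_id,
    sample_type).

    Duplicate (patient, sample_type) expression barcodes are collapsed to the
    first occurrence with a logged warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    counts.index.name = "gene"
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate gene symbol: {dup!r}")
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna() & counts.notna()
    if bad_mask.to_numpy().any():
        g, s = np.argwhere(bad_mask.to_numpy())[0]
        raise FormatError(
            f"non-numeric count {counts.iat[g, s]!r} at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"negative count {counts.iat[g, s]} at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    counts = numeric.astype(np.int64)

    meta = pd.read_csv(samples_path, sep="\t", dtype=str)
    _require_columns(meta, ["sample_id", "patient_id", "sample_type"], "sample metadata")
    meta = meta.set_index("sample_id")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise FormatError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[counts.columns]

    dup_mask = meta.duplicated(subset=["patient_id", "sample_type"], keep="first")
    if dup_mask.any():
        logger.warning(
            "collapsed %d duplicate patient barcodes to first occurrence",
            int(dup_mask.sum()),
        )
        keep = meta.index[~dup_mask]
        counts = counts[keep]
        meta = meta.loc[keep]

    return ExpressionMatrix(
        counts=counts,
        sample_type=meta["sample_type"].rename("sample_type"),
        patient_id=meta["patient_id"].rename("patient_id"),
    )


def write_expression(matrix: ExpressionMatrix, counts_path, samples_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", lineterminator="\n")
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "patient_id": matrix.patient_id.values,
            "sample_type": matrix.sample_type.values,
        }
    )
    meta.to_csv(samples_path, sep="\t", index=False, lineterminator="\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    df = df[CLINICAL_COLUMNS].copy()
    vs = df["vital_status"].str.strip().str.lower()
    unknown = vs.notna() & ~vs.isin(["alive", "dead"])
    if unknown.any():
        logger.warning("clinical: %d rows with unrecognized vital_status set missing",
                       int(unknown.sum()))
    df["vital_status"] = vs.where(vs.isin(["alive", "dead"]))
    for col in ("days_to_death", "days_to_last_follow_up"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_maf(path) -> MutationTable:
    """Read a MAF file (standard columns) or the minimal TSV dialect.

    Records whose protein position cannot be parsed are retained with a
    missing position (they are counted but unusable for clustering).
    An empty file (header only) yields a zero-record table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if all(c in df.columns for c in MAF_COLUMNS.values()):
        cols = MAF_COLUMNS
        classes = df[cols["variant_class"]].str.strip().str.lower().map(
            lambda v: _MAF_CLASS_MAP.get(v, "other")
        )
    elif all(c in df.columns for c in MAF_MINIMAL_COLUMNS.values()):
        cols = MAF_MINIMAL_COLUMNS
        classes = df[cols["variant_class"]].str.strip().str.lower()
        bad = set(classes.dropna()) - set(VARIANT_CLASSES)
        if bad:
            raise FormatError(f"unknown variant classes: {sorted(bad)}")
    else:
        raise FormatError(
            "mutation file: expected standard MAF header "
            f"{list(MAF_COLUMNS.values())} or minimal header "
            f"{list(MAF_MINIMAL_COLUMNS.values())}; got {list(df.columns)}"
        )
    positions = df[cols["position"]].map(parse_protein_position)
    n_unusable = int(positions.isna().sum())
    if n_unusable:
        logger.info("mutation file: %d records without usable protein position",
                    n_unusable)
    records = pd.DataFrame(
        {
            "gene": df[cols["gene"]],
            "protein_position": pd.array(positions, dtype="Int64"),
            "variant_class": classes,
            "sample": df[cols["sample"]],
        }
    )
    return MutationTable(records)


def write_maf(mutations: MutationTable, path) -> None:
    """Write mutations using the standard MAF column names (position in the
    position/length dialect is not reconstructed; plain integers are valid)."""
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mutations.records["gene"],
            "Protein_position": mutations.records["protein_position"].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            ),
            "Variant_Classification": mutations.records["variant_class"].map(
                _CANONICAL_TO_MAF
            ),
            "Tumor_Sample_Barcode": mutations.records["sample"],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


_CANONICAL_TO_MAF = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "insertion": "In_Frame_Ins",
    "deletion": "In_Frame_Del",
    "silent": "Silent",
    "other": "Other",
}


def read_annotations(path) -> AnnotationCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, [c for c in ANNOTATION_COLUMNS if c != "protein_length"],
                     "annotation catalog")
    df = df.copy()
    df["understudied"] = df["understudied"].str.strip().str.lower().isin(
        ["true", "1", "yes"]
    )
    if "protein_length" in df.columns:
        df["protein_length"] = pd.to_numeric(df["protein_length"], errors="coerce").astype(
            "Int64"
        )
    else:
        df["protein_length"] = pd.array([pd.NA] * len(df), dtype="Int64")
    for col in ("moa_target_cancers", "in_trial_cancers"):
        df[col] = df[col].fillna("")
    return AnnotationCatalog(df.set_index("gene"))


def write_annotations(catalog: AnnotationCatalog, path) -> None:
    df = catalog.table.reset_index().copy()
    df["understudied"] = df["understudied"].map(lambda b: "true" if b else "false")
    df["protein_length"] = df["protein_length"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dependency(scores_path, cell_lines_path) -> DependencyMatrix:
    scores = pd.read_csv(scores_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    scores.index.name = "gene"
    meta = pd.read_csv(cell_lines_path, sep="\t", dtype=str)
    _require_columns(meta, ["cell_line", "tissue"], "cell line metadata")
    mapping = meta.set_index("cell_line")["tissue"]
    return DependencyMatrix(scores=scores.astype(float), cell_line_tissue=mapping)


def write_dependency(dep: DependencyMatrix, scores_path, cell_lines_path) -> None:
    # %.17g guarantees the float round-trips bit-exactly through the TSV
    dep.scores.to_csv(scores_path, sep="\t", lineterminator="\n",
                      float_format="%.17g")
    meta = pd.DataFrame(
        {"cell_line": dep.cell_line_tissue.index, "tissue": dep.cell_line_tissue.values}
    )
    meta.to_csv(cell_lines_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# scorecard output
# ---------------------------------------------------------------------------

SCORECARD_COLUMNS = [
    "gene",
    "cohort",
    "dge",
    "survival",
    "hotspot",
    "clinical_T",
    "clinical_N",
    "clinical_M",
    "clinical_grade",
    "clinical_pathologic_stage",
    "clinical_clinical_stage",
    "raw",
    "max",
    "cki_percent",
    "rank",
    "tdl",
    "understudied",
    "moa_target",
]


def write_scorecards(cards: Sequence, tsv_path, json_path=None,
                     header: Optional[Mapping[str, object]] = None) -> None:
    """Write ranked scorecards as a deterministic-ordered TSV (descending CKI
    then lexicographic gene) plus an optional JSON summary.

    ``header`` entries (e.g. seed, config hash) are embedded as ``#`` comment
    lines at the top of the TSV.
    """
    rows = []
    for c in cards:
        row = {
            "gene": c.gene,
            "cohort": c.cohort,
            "dge": _fmt_component(c.dge_component),
            "survival": _fmt_component(c.survival_component),
            "hotspot": _fmt_component(c.hotspot_component),
            "raw": f"{c.raw_score:.4f}",
            "max": c.max_score,
            "cki_percent": f"{c.cki_percent:.2f}",
            "rank": c.rank,
            "tdl": c.tdl,
            "understudied": "true" if c.understudied else "false",
            "moa_target": "true" if c.moa_target else "false",
        }
        for param, col in (
            ("T", "clinical_T"),
            ("N", "clinical_N"),
            ("M", "clinical_M"),
            ("grade", "clinical_grade"),
            ("pathologic_stage", "clinical_pathologic_stage"),
            ("clinical_stage", "clinical_clinical_stage"),
        ):
            val = c.clinical_components.get(param)
            row[col] = "" if val is None else f"{val:.4f}"
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCORECARD_COLUMNS)
    df = df.sort_values(["rank", "gene"], kind="mergesort")

    tsv_path = Path(tsv_path)
    with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    if json_path is not None:
        ckis = [c.cki_percent for c in cards]
        summary = {
            "n_genes": len(cards),
            "cohort": cards[0].cohort if cards else None,
            "mean_cki": float(np.mean(ckis)) if ckis else None,
            "max_cki": float(np.max(ckis)) if ckis else None,
            "top_gene": min(
                (c for c in cards if c.rank == 1), key=lambda c: c.gene
            ).gene if cards else None,
            "n_dge": int(sum((c.dge_component or 0) for c in cards)),
            "n_survival": int(sum((c.survival_component or 0) for c in cards)),
            "n_hotspot": int(sum((c.hotspot_component or 0) for c in cards)),
        }
        if header:
            summary["run"] = {k: str(v) for k, v in header.items()}
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fmt_component(val) -> str:
    return "" if val is None else str(int(val))


def read_scorecard_table(path) -> pd.DataFrame:
    """Read a scorecard TSV back into a DataFrame (comment header skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
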