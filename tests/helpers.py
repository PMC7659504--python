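"""Shared constructors for small in-memory test objects."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cki.io_formats import ClinicalTable, ExpressionMatrix, MutationTable


def make_matrix(counts: dict[str, list[int]], n_tumor: int) -> ExpressionMatrix:
    """Expression matrix from {gene: counts}; the first ``n_tumor`` samples
    are primary tumors, the rest normals, one patient per sample."""
    df = pd.DataFrame(counts).T
    n = df.shape[1]
    samples = [f"S{i:02d}" for i in range(n)]
    df.columns = samples
    df.index.name = "gene"
    types = ["01"] * n_tumor + ["11"] * (n - n_tumor)
    return ExpressionMatrix(
        counts=df.astype(np.int64),
        sample_type=pd.Series(types, index=samples, name="sample_type"),
        patient_id=pd.Series([f"P{i:02d}" for i in range(n)], index=samples,
                             name="patient_id"),
    )


def make_records(times, events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool),
        }
    )


def make_mutations(rows) -> MutationTable:
    """rows: iterable of (gene, position, variant_class, sample)."""
    rows = list(rows)
    if not rows:
        return MutationTable(pd.DataFrame(
            {"gene": pd.Series(dtype=str),
             "protein_position": pd.Series(dtype="Int64"),
             "variant_class": pd.Series(dtype=str),
             "sample": pd.Series(dtype=str)}))
    df = pd.DataFrame(rows, columns=["gene", "protein_position", "variant_class",
                                     "sample"])
    df["protein_position"] = df["protein_position"].astype("Int64")
    return MutationTable(df)


def make_clinical(rows) -> ClinicalTable:
    """rows: list of dicts with any subset of the clinical columns."""
    base = {c: None for c in ("vital_status", "days_to_death",
                              "days_to_last_follow_up", "t_stage", "n_stage",
                              "m_stage", "grade", "pathologic_stage",
                              "clinical_stage")}
    full = []
    for i, row in enumerate(rows):
        rec = {"patient_id": row.get("patient_id", f"P{i:02d}"), **base, **row}
        full.append(rec)
    df = pd.DataFrame(full)
    for col in ("days_to_death", "days_to_last_follow_up"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)
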