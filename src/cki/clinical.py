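"""Expression-stage correlation scoring over TNM, grade, and stage labels.

Raw substage labels are collapsed to canonical ordinal levels (t1b1 -> T1,
n3a -> N3, m1 -> M1, g3 -> grade 3, "stage iiia" -> 3). For each clinical
parameter, expression is tested across levels by one-way ANOVA and, for the
score, by directional pairwise Welch tests: a level pair counts only when
expression is significantly HIGHER at the more advanced level. The
per-parameter score is the fraction of tested pairs that count (zero when
none does), so it always lies in [0, 1] — one fully concordant parameter
contributes at most 1 to the clinical total.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable

#: clinical parameters in canonical order, with the raw clinical-table column
#: and the admissible level range for each
PARAMETERS: dict[str, tuple[str, range]] = {
    "T": ("t_stage", range(1, 5)),
    "N": ("n_stage", range(0, 4)),
    "M": ("m_stage", range(0, 2)),
    "grade": ("grade", range(1, 5)),
    "pathologic_stage": ("pathologic_stage", range(1, 5)),
    "clinical_stage": ("clinical_stage", range(1, 5)),
}

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


@dataclass
class ClinicalScore:
    """Per-parameter scores in [0, 1] plus their sum; parameters without
    sufficient data are absent from both the scores and the maximum."""

    per_parameter: dict[str, float]
    clinical_total: float
    parameters_available: int


def collapse_substages(raw, parameter: str) -> Optional[int]:
    """Map a free-text substage label to its canonical ordinal level.

    Case-insensitive prefix rule: the leading letter plus first digit decides
    the level (``t1b1`` -> 1, ``n2c`` -> 2). Pathologic/clinical stage labels
    use roman numerals (``stage iib`` -> 2). Labels without a digit or
    numeral (``tx``, ``nx``, ``mx``) and out-of-range levels map to missing.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if not text:
        return None
    if parameter in ("pathologic_stage", "clinical_stage"):
        m = re.match(r"^(?:stage\s*)?(iv|iii|ii|i)(?:[a-c][0-9]?)?\b", text)
        level = _ROMAN[m.group(1)] if m else None
    else:
        prefix = {"T": "t", "N": "n", "M": "m", "grade": "g"}[parameter]
        m = re.match(rf"^{prefix}\s*(\d)", text)
        level = int(m.group(1)) if m else None
    if level is None or level not in PARAMETERS[parameter][1]:
        return None
    return level


def stage_assignments(clinical: ClinicalTable) -> pd.DataFrame:
    """Patient x parameter table of canonical levels (nullable Int64)."""
    df = clinical.table
    out = pd.DataFrame(index=pd.Index(df["patient_id"], name="patient_id"))
    for param, (column, _) in PARAMETERS.items():
        out[param] = pd.array(
            [collapse_substages(v, param) for v in df[column]], dtype="Int64"
        )
    return out


def _usable_levels(levels: pd.Series, min_per_level: int = 2) -> list[int]:
    counts = levels.dropna().astype(int).value_counts()
    return sorted(int(l) for l in counts.index[counts >= min_per_level])


def stage_anova(expression, levels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of expression grouped by stage level.

    Requires at least two levels with at least two patients each; otherwise
    the parameter is unavailable and a ValueError is raised.
    """
    expression = pd.Series(np.asarray(expression, dtype=float))
    levels = pd.Series(pd.array(levels, dtype="Int64"), index=expression.index)
    usable = _usable_levels(levels)
    if len(usable) < 2:
        raise ValueError("ANOVA needs >=2 levels with >=2 patients each")
    groups = [expression[levels == l].to_numpy() for l in usable]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 0.0, 1.0  # all observations identical
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


def pairwise_stage_score(expression, levels, alpha: float = 0.05,
                         pairs: str = "all", rule: str = "average") -> float:
    """Directional pairwise score for one parameter.

    For each tested pair of observed levels (i < j), a two-sided Welch test
    is run; the pair counts iff p < alpha AND the mean at the higher level
    exceeds the mean at the lower level. ``rule="average"`` (default) scores
    counting/tested pairs; ``rule="any"`` scores 1 when any pair counts.
    ``pairs`` selects all ordered pairs or consecutive levels only.
    """
    if pairs not in ("all", "consecutive"):
        raise ValueError("pairs must be 'all' or 'consecutive'")
    if rule not in ("average", "any"):
        raise ValueError("rule must be 'average' or 'any'")
    expression = pd.Series(np.asarray(expression, dtype=float))
    levels = pd.Series(pd.array(levels, dtype="Int64"), index=expression.index)
    usable = _usable_levels(levels)
    if len(usable) < 2:
        raise ValueError("pairwise scoring needs >=2 levels with >=2 patients each")
    if pairs == "all":
        tested = list(itertools.combinations(usable, 2))
    else:
        tested = [(usable[k], usable[k + 1]) for k in range(len(usable) - 1)]
    n_counting = 0
    for lo, hi in tested:
        x = expression[levels == lo].to_numpy()
        y = expression[levels == hi].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(y, x, equal_var=False)
        if not np.isnan(p) and p < alpha and y.mean() > x.mean():
            n_counting += 1
    if n_counting == 0:
        return 0.0
    if rule == "any":
        return 1.0
    return n_counting / len(tested)


def available_parameters(assignments: pd.DataFrame,
                         parameters: Sequence[str] | None = None) -> list[str]:
    """Parameters with at least two levels of at least two patients each."""
    parameters = parameters or list(PARAMETERS)
    return [
        p for p in parameters if len(_usable_levels(assignments[p])) >= 2
    ]


def clinical_score(expression: pd.Series, assignments: pd.DataFrame,
                   parameters: Sequence[str] | None = None,
                   alpha: float = 0.05, pairs: str = "all",
                   rule: str = "average") -> ClinicalScore:
    """Sum of per-parameter pairwise scores for one gene.

    ``expression`` is per-patient tumor expression; ``assignments`` come from
    :func:`stage_assignments`. Parameters without sufficient data (fewer than
    two usable levels among the expressed patients) are excluded from both
    the total and the cohort's maximum score.
    """
    shared = assignments.index.intersection(expression.index)
    expr = expression.loc[shared]
    per_param: dict[str, float] = {}
    for param in (parameters or list(PARAMETERS)):
        levels = assignments.loc[shared, param]
        if len(_usable_levels(levels)) < 2:
            continue
        per_param[param] = pairwise_stage_score(
            expr.to_numpy(), levels.to_numpy(), alpha=alpha, pairs=pairs, rule=rule
        )
    return ClinicalScore(
        per_parameter=per_param,
        clinical_total=float(sum(per_param.values())),
        parameters_available=len(per_param),
    )


def clinical_scores_matrix(expression: pd.DataFrame, assignments: pd.DataFrame,
                           parameters: Sequence[str] | None = None,
                           alpha: float = 0.05, pairs: str = "all",
                           rule: str = "average") -> pd.DataFrame:
    """Per-parameter scores for many genes at once.

    ``expression`` is genes x patients; equivalent to calling
    :func:`clinical_score` per gene (all genes share the patient set, so the
    usable levels are cohort-wide) but runs each pairwise Welch test once,
    vectorized over genes. Columns cover only available parameters.
    """
    if rule not in ("average", "any"):
        raise ValueError("rule must be 'average' or 'any'")
    shared = assignments.index.intersection(expression.columns)
    expr = expression[shared]
    out: dict[str, np.ndarray] = {}
    for param in (parameters or list(PARAMETERS)):
        levels = assignments.loc[shared, param]
        usable = _usable_levels(levels)
        if len(usable) < 2:
            continue
        if pairs == "all":
            tested = list(itertools.combinations(usable, 2))
        elif pairs == "consecutive":
            tested = [(usable[k], usable[k + 1]) for k in range(len(usable) - 1)]
        else:
            raise ValueError("pairs must be 'all' or 'consecutive'")
        counting = np.zeros(len(expr), dtype=float)
        for lo, hi in tested:
            lo_mask = (levels == lo).fillna(False).to_numpy(dtype=bool)
            hi_mask = (levels == hi).fillna(False).to_numpy(dtype=bool)
            x = expr.loc[:, lo_mask].to_numpy()
            y = expr.loc[:, hi_mask].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(y, x, axis=1, equal_var=False)
            hit = (~np.isnan(p)) & (p < alpha) & (y.mean(axis=1) > x.mean(axis=1))
            counting += hit
        if rule == "any":
            scores = (counting > 0).astype(float)
        else:
            scores = counting / len(tested)
        out[param] = scores
    return pd.DataFrame(out, index=expr.index)
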