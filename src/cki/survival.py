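"""Expression-stratified survival scoring.

Patients are split at the 25th/75th percentiles of a gene's tumor expression;
the upper- and lower-quartile arms are compared with the two-group log-rank
test on Kaplan-Meier (product-limit) curves. A gene earns the binary survival
component iff the test is significant AND the high-expression arm is the
worse arm, measured by restricted mean survival time up to the shorter arm's
follow-up horizon — high expression must predict shorter survival, not merely
different survival.

The Kaplan-Meier estimator and the log-rank statistic are implemented
directly (they are the scoring primitives); `lifelines` serves as an
independent cross-check in the test suite. Ties between a death and a
censoring at the same time follow the standard convention: deaths first, the
censored patient still counts as at risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class KmCurve:
    """Product-limit estimate defined at the observed event times."""

    event_times: np.ndarray  # strictly increasing
    survival: np.ndarray  # S(t) just after each event time, non-increasing
    at_risk: np.ndarray  # n_i at each event time
    n_events: np.ndarray  # d_i at each event time


def build_survival_records(clinical: ClinicalTable) -> pd.DataFrame:
    """Per-patient (time, event) pairs.

    dead -> (days_to_death, event); alive -> (days_to_last_follow_up,
    censored). Patients with missing vital status, or with a missing or
    non-positive time, carry no usable time-to-event information and are
    excluded with a logged count.
    """
    df = clinical.table
    time = np.where(df["vital_status"] == "dead",
                    df["days_to_death"], df["days_to_last_follow_up"])
    time = pd.to_numeric(pd.Series(time, index=df.index), errors="coerce")
    event = df["vital_status"] == "dead"
    usable = df["vital_status"].isin(["alive", "dead"]) & time.notna() & (time > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("survival: excluded %d patients without usable time/status",
                    n_excluded)
    out = pd.DataFrame(
        {
            "patient_id": df.loc[usable, "patient_id"].values,
            "time": time[usable].astype(float).values,
            "event": event[usable].values,
        }
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def km_curve(records: pd.DataFrame) -> KmCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    if len(records) == 0:
        raise ValueError("km_curve needs at least one record")
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int((times >= t).sum())
        n_events[i] = int((events & (times == t)).sum())
    survival = np.cumprod(1.0 - n_events / at_risk)
    return KmCurve(event_times=event_times, survival=survival,
                   at_risk=at_risk, n_events=n_events)


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (sum(O_A - E_A))^2 / sum(V), p from
    a chi-square distribution with one degree of freedom."""
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("log-rank test needs two non-empty groups")
    ta = records_a["time"].to_numpy(dtype=float)
    ea = records_a["event"].to_numpy(dtype=bool)
    tb = records_b["time"].to_numpy(dtype=float)
    eb = records_b["event"].to_numpy(dtype=bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int((ea & (ta == t)).sum())
        d2 = int((eb & (tb == t)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def restricted_mean_survival(curve: KmCurve, tau: float) -> float:
    """Area under the KM step function on [0, tau]; S(t) = 1 before the first
    event."""
    if tau <= 0:
        return 0.0
    rmst = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(curve.event_times, curve.survival):
        if t >= tau:
            break
        rmst += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    rmst += prev_s * (tau - prev_t)
    return rmst


def survival_score(expression: pd.Series, records: pd.DataFrame,
                   alpha: float = 0.05, q_low: float = 0.25,
                   q_high: float = 0.75) -> tuple[int, dict]:
    """Binary survival component for one gene.

    ``expression`` is per-patient tumor expression (indexed by patient_id);
    ``records`` come from :func:`build_survival_records`. Patients between
    the quartile boundaries are excluded; boundary ties go to the extreme
    arms. Returns (score, detail) where detail records the test and the
    reason whenever the score is 0.
    """
    merged = records.merge(
        expression.rename("expr"), left_on="patient_id", right_index=True
    )
    detail: dict = {"n": len(merged)}
    if len(merged) < 8:
        detail["reason"] = "insufficient"
        return 0, detail
    lo, hi = np.quantile(merged["expr"], [q_low, q_high])
    high = merged[merged["expr"] >= hi]
    low = merged[(merged["expr"] <= lo) & (merged["expr"] < hi)]
    detail.update(n_high=len(high), n_low=len(low))
    if len(high) < 2 or len(low) < 2:
        detail["reason"] = "insufficient"
        return 0, detail
    chi2, p = logrank_test(high, low)
    detail.update(chi2=chi2, p_value=p)
    if p >= alpha:
        detail["reason"] = "not significant"
        return 0, detail
    tau = min(high["time"].max(), low["time"].max())
    rmst_high = restricted_mean_survival(km_curve(high), tau)
    rmst_low = restricted_mean_survival(km_curve(low), tau)
    detail.update(rmst_high=rmst_high, rmst_low=rmst_low, tau=tau)
    if rmst_high >= rmst_low:
        detail["reason"] = "high arm not worse"
        return 0, detail
    return 1, detail
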