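"""Survival stratification: Kaplan-Meier, log-rank, cutpoint selection.

Patients are stratified either by the median of a CAF-subset abundance
(high = strictly above the median) or, for bulk expression scores, by a
maximally selected log-rank cutpoint: the cutpoint over all admissible
candidate values that maximises the absolute standardized two-group
log-rank statistic, subject to both groups holding at least a ``minprop``
fraction of patients.  The composite CAF-S5 bulk phenotype is FAP high
AND PDPN high AND aSMA low at each marker's selected cutpoint.

Kaplan-Meier estimation and log-rank p-values are delegated to
lifelines; the cutpoint search runs on an internal vectorised two-group
log-rank score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .profiles import SchemaError

__all__ = [
    "KMCurve",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "logrank_score",
    "median_split",
    "max_selected_cutpoint",
    "assign_bulk_phenotype",
    "truncate_followup",
    "FIVE_YEARS_DAYS",
]

#: Follow-up horizon for 5-year survival analyses.
FIVE_YEARS_DAYS: float = 1826.0


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray       # distinct event/censoring times, ascending
    at_risk: np.ndarray     # risk-set size entering each time
    survival: np.ndarray    # S(t) just after each time

    def probability_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CutpointResult:
    """Maximally selected log-rank cutpoint for one covariate."""

    marker: str
    cutpoint: float
    statistic: float     # standardized log-rank statistic at the cutpoint
    n_high: int
    n_low: int
    minprop: float


def _check_table(table: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in table.columns:
            raise SchemaError(f"survival table missing column {col!r}")
    if (table["time"] < 0).any():
        raise SchemaError("negative survival times")
    if not table["event"].isin((0, 1)).all():
        raise SchemaError("event flags must be 0/1")


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    _check_table(table)
    if len(table) == 0:
        raise ValueError("need at least one patient")
    kmf = KaplanMeierFitter().fit(table["time"], table["event"])
    et = kmf.event_table
    mask = (et["observed"] + et["censored"]).to_numpy() > 0
    times = et.index.to_numpy(dtype=float)[mask]
    at_risk = et["at_risk"].to_numpy()[mask]
    surv = (kmf.survival_function_["KM_estimate"]
            .reindex(et.index[mask]).to_numpy())
    return KMCurve(times=times, at_risk=at_risk, survival=surv)


def logrank_test(groups: list[pd.DataFrame]) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi2, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        _check_table(g)
        if len(g) == 0:
            raise ValueError("a group has zero patients")
    time = np.concatenate([g["time"].to_numpy(dtype=float) for g in groups])
    event = np.concatenate([g["event"].to_numpy() for g in groups])
    label = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    if event.sum() == 0:
        return 0.0, len(groups) - 1, 1.0  # no events: trivially null
    res = multivariate_logrank_test(time, label, event)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def logrank_score(
    time: np.ndarray, event: np.ndarray, in_group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank score U = sum(O - E) and its variance V.

    Observed-minus-expected events in the ``in_group`` arm with the
    hypergeometric variance at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_group = np.asarray(in_group, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], in_group[order]
    n = len(t)

    U = 0.0
    V = 0.0
    i = 0
    n_risk = n
    n1_risk = int(g.sum())
    while i < n:
        j = i
        d = d1 = removed = removed1 = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            d1 += e[j] * g[j]
            removed += 1
            removed1 += int(g[j])
            j += 1
        if d > 0 and n_risk > 1:
            frac = n1_risk / n_risk
            U += d1 - d * frac
            V += d * frac * (1 - frac) * (n_risk - d) / (n_risk - 1)
        n_risk -= removed
        n1_risk -= removed1
        i = j
    return U, V


def median_split(table: pd.DataFrame, covariate: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split patients at the covariate median: (high, low).

    High is strictly above the median; values at the median go to the
    low group.  A constant covariate cannot be split.
    """
    _check_table(table)
    if covariate not in table.columns:
        raise SchemaError(f"missing covariate column {covariate!r}")
    if table[covariate].isna().any():
        raise SchemaError(f"covariate {covariate!r} has missing values")
    med = float(table[covariate].median())
    high = table[table[covariate] > med]
    low = table[table[covariate] <= med]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(f"degenerate split: covariate {covariate!r} constant")
    return high, low


def max_selected_cutpoint(
    table: pd.DataFrame,
    covariate: str,
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for one covariate.

    Candidate cutpoints are midpoints between adjacent sorted unique
    covariate values; a candidate is admissible when both resulting
    groups contain at least ``minprop * n`` patients.  The admissible
    cutpoint maximising ``|U / sqrt(V)|`` wins, ties going to the
    smallest cutpoint.  The selection p-value correction for maximal
    selection is not applied; downstream significance is assessed by an
    ordinary log-rank test on the chosen split.
    """
    _check_table(table)
    if covariate not in table.columns:
        raise SchemaError(f"missing covariate column {covariate!r}")
    x = table[covariate].to_numpy(dtype=float)
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy()
    n = len(table)
    uniq = np.unique(x)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    best: CutpointResult | None = None
    min_n = minprop * n
    for c in candidates:
        high = x > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < min_n or n_low < min_n:
            continue
        U, V = logrank_score(time, event, high)
        if V <= 0:
            continue
        z = U / np.sqrt(V)
        if best is None or abs(z) > abs(best.statistic) + 1e-12:
            best = CutpointResult(covariate, float(c), float(z),
                                  n_high, n_low, minprop)
    if best is None:
        raise ValueError(f"no admissible cutpoint for {covariate!r} "
                         f"at minprop={minprop}")
    return best


def assign_bulk_phenotype(
    table: pd.DataFrame,
    cutpoints: dict[str, CutpointResult],
) -> pd.Series:
    """Composite CAF-S5 bulk phenotype from three marker cutpoints.

    A patient is CAF-S5 when FAP and PDPN are above their cutpoints and
    aSMA is at or below its cutpoint; everyone else is 'other'.
    """
    for marker in ("FAP", "PDPN", "aSMA"):
        if marker not in cutpoints:
            raise SchemaError(f"missing cutpoint for {marker}")
        if marker not in table.columns:
            raise SchemaError(f"missing marker score column {marker}")
    s5 = (
        (table["FAP"] > cutpoints["FAP"].cutpoint)
        & (table["PDPN"] > cutpoints["PDPN"].cutpoint)
        & (table["aSMA"] <= cutpoints["aSMA"].cutpoint)
    )
    return pd.Series(np.where(s5, "CAF-S5", "other"),
                     index=table.index, name="phenotype")


def truncate_followup(table: pd.DataFrame, horizon: float = FIVE_YEARS_DAYS) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` days.

    Patients with time beyond the horizon are censored there; events
    within the horizon are unchanged (truncation never adds events).
    """
    _check_table(table)
    out = table.copy()
    beyond = out["time"] > horizon
    out.loc[beyond, "time"] = horizon
    out.loc[beyond, "event"] = 0
    return out
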