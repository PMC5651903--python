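"""Kaplan-Meier estimation, the two-group log-rank test, and the
Mantel-Haenszel (O/E) hazard ratio, implemented from first principles.

Conventions: subjects censored exactly at an event time are still at risk
for that event (the standard product-limit convention); follow-up can be
administratively restricted to a horizon (default 120 months, i.e. ten
years) by censoring later times at the horizon.  The hazard ratio between
two strata is (O_1/E_1)/(O_2/E_2) with log-scale standard error
sqrt(1/E_1 + 1/E_2); a univariate Cox fit on the binary group indicator is
available for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurvivalTable
from .signature import StrataAssignment

log = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogRankResult",
    "HazardRatioEstimate",
    "restrict_followup",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
]


@dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    n_at_risk: np.ndarray    # at risk at each event time
    n_events: np.ndarray     # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    statistic: float
    p: float


@dataclass
class HazardRatioEstimate:
    hr: float
    se_log: float
    ci_low: float
    ci_high: float
    observed: dict[str, float]
    expected: dict[str, float]
    method: str = "mantel-haenszel"


def restrict_followup(table: SurvivalTable, horizon_months: float = 120.0) -> SurvivalTable:
    """Censor all follow-up beyond ``horizon_months`` at the horizon."""
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    df = table.data.copy()
    over = df["time"] > horizon_months
    df.loc[over, "time"] = horizon_months
    df.loc[over, "event"] = 0
    return SurvivalTable(df)


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    if len(table) == 0:
        raise ValueError("cannot estimate a survival curve from an empty table")
    times = table.data["time"].to_numpy()
    events = table.data["event"].to_numpy()
    event_times = np.unique(times[events == 1])
    n_at_risk = np.empty(len(event_times), dtype=np.int64)
    n_events = np.empty(len(event_times), dtype=np.int64)
    surv = np.empty(len(event_times))
    s = 1.0
    for i, t in enumerate(event_times):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        n_at_risk[i] = at_risk
        n_events[i] = d
        surv[i] = s
    return KMCurve(times=event_times, survival=surv, n_at_risk=n_at_risk, n_events=n_events)


def _two_group_oe(
    table: SurvivalTable, strata: StrataAssignment, groups: tuple[str, str]
) -> tuple[dict[str, float], dict[str, float], float]:
    """Observed/expected events per group and the hypergeometric variance,
    accumulated over distinct event times."""
    g1, g2 = groups
    labels = strata.labels
    df = table.data.set_index("sample_id")
    members = {g: [s for s in labels.index[labels == g] if s in df.index] for g in groups}
    for g in groups:
        if not members[g]:
            raise ValueError(f"group {g!r} has no subjects in the survival table")
    t1 = df.loc[members[g1], "time"].to_numpy()
    e1 = df.loc[members[g1], "event"].to_numpy()
    t2 = df.loc[members[g2], "time"].to_numpy()
    e2 = df.loc[members[g2], "event"].to_numpy()
    all_times = np.concatenate([t1, t2])
    all_events = np.concatenate([e1, e2])
    event_times = np.unique(all_times[all_events == 1])
    o1 = float(e1.sum())
    o2 = float(e2.sum())
    exp1 = 0.0
    exp2 = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        n = n1 + n2
        d = int(((all_times == t) & (all_events == 1)).sum())
        exp1 += d * n1 / n
        exp2 += d * n2 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (n2 / n)
    return (
        {g1: o1, g2: o2},
        {g1: exp1, g2: exp2},
        var,
    )


def logrank_test(
    table: SurvivalTable,
    strata: StrataAssignment,
    groups: tuple[str, str] = ("high", "low"),
) -> LogRankResult:
    """Two-group log-rank test; chi-square with 1 df."""
    observed, expected, var = _two_group_oe(table, strata, groups)
    g1 = groups[0]
    if sum(observed.values()) == 0 or var == 0:
        log.warning("no events (or zero variance); log-rank statistic set to 0, p = 1")
        return LogRankResult(observed, expected, var, 0.0, 1.0)
    statistic = (observed[g1] - expected[g1]) ** 2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(observed, expected, var, float(statistic), p)


def hazard_ratio(
    table: SurvivalTable,
    strata: StrataAssignment,
    groups: tuple[str, str] = ("high", "low"),
    method: str = "mantel-haenszel",
) -> HazardRatioEstimate:
    """Hazard ratio of groups[0] relative to groups[1].

    Default is the Mantel-Haenszel (O/E ratio) estimate from the log-rank
    table; ``method="cox"`` fits a univariate Cox model on the binary group
    indicator instead (Breslow tie handling).
    """
    observed, expected, _ = _two_group_oe(table, strata, groups)
    g1, g2 = groups
    if method == "cox":
        beta, se = _cox_binary(table, strata, groups)
        hr = math.exp(beta)
        return HazardRatioEstimate(
            hr=hr,
            se_log=se,
            ci_low=math.exp(beta - 1.96 * se),
            ci_high=math.exp(beta + 1.96 * se),
            observed=observed,
            expected=expected,
            method="cox",
        )
    if method != "mantel-haenszel":
        raise ValueError(f"unknown hazard ratio method {method!r}")
    if expected[g1] == 0 or expected[g2] == 0 or observed[g2] == 0:
        raise ValueError("a group has zero (expected) events; hazard ratio undefined")
    hr = (observed[g1] / expected[g1]) / (observed[g2] / expected[g2])
    se = math.sqrt(1.0 / expected[g1] + 1.0 / expected[g2])
    log_hr = math.log(hr)
    return HazardRatioEstimate(
        hr=hr,
        se_log=se,
        ci_low=math.exp(log_hr - 1.96 * se),
        ci_high=math.exp(log_hr + 1.96 * se),
        observed=observed,
        expected=expected,
    )


def _cox_binary(
    table: SurvivalTable, strata: StrataAssignment, groups: tuple[str, str]
) -> tuple[float, float]:
    """Newton-Raphson fit of a Cox model with a single 0/1 covariate
    (1 = groups[0]); Breslow approximation for tied event times."""
    labels = strata.labels
    df = table.data.set_index("sample_id")
    keep = [s for s in labels.index if s in df.index and labels[s] in groups]
    x = np.array([1.0 if labels[s] == groups[0] else 0.0 for s in keep])
    t = df.loc[keep, "time"].to_numpy()
    e = df.loc[keep, "event"].to_numpy()
    event_times = np.unique(t[e == 1])
    beta = 0.0
    for _ in range(50):
        score = 0.0
        info = 0.0
        for tt in event_times:
            at_risk = t >= tt
            d_mask = (t == tt) & (e == 1)
            d = d_mask.sum()
            w = np.exp(beta * x[at_risk])
            s0 = w.sum()
            s1 = (w * x[at_risk]).sum()
            score += x[d_mask].sum() - d * s1 / s0
            info += d * (s1 / s0) * (1 - s1 / s0)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < 1e-10:
            break
    return beta, (1.0 / math.sqrt(info) if info > 0 else float("inf"))
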