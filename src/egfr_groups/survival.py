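"""Retrospective outcome statistics: Kaplan-Meier curves and medians,
Mantel-Cox log-rank tests with O/E-based hazard ratios, stratified
time-to-event layouts, and response-rate (ORR) contingency analysis.

Endpoints follow the retrospective-oncology conventions: TTF (time from
TKI start to radiologic progression, discontinuation or death), DOT
(duration of treatment), OS and PFI.  Hazard ratios are the
Mantel-Haenszel/log-rank form ``(O_A/E_A)/(O_B/E_B)`` with a CI of
``exp(log HR +/- 1.96 * sqrt(1/E_A + 1/E_B))`` -- the estimator behind
the reported figures, deliberately not a Cox regression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter

__all__ = [
    "KaplanMeierResult",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "StratifiedOutcomes",
    "stratified_outcomes",
    "OrrResult",
    "orr_analysis",
    "RESPONSE_CATEGORIES",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


@dataclass
class KaplanMeierResult:
    """Product-limit estimate with the step function and median.

    ``median`` is the smallest time with S(t) <= 0.5 (the earliest such
    time if S sits exactly at 0.5 over an interval); NaN when S never
    reaches 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int
    fitter: KaplanMeierFitter

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return float(s)

    def plot(self, ax=None, **kwargs):
        return self.fitter.plot_survival_function(ax=ax, **kwargs)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeierResult:
    """Kaplan-Meier estimator; ties decrement simultaneously."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = grid > 0
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return KaplanMeierResult(
        times=grid[keep],
        survival=surv[keep],
        median=median,
        n=int(times.size),
        n_events=int(events.sum()),
        fitter=kmf,
    )


@dataclass
class LogrankResult:
    """Two-sided Mantel-Cox log-rank test with O/E hazard ratio.

    ``hazard_ratio`` has group A in the numerator:
    ``(O_A/E_A)/(O_B/E_B)``.
    """

    chi_square: float
    p_value: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float
    table: pd.DataFrame  # per-event-time 2x2 contributions

    def summary(self) -> str:
        return (
            f"Mantel-Cox log-rank: chi2 = {self.chi_square:.4g}, p = {self.p_value:.3g}; "
            f"HR (A/B) = {self.hazard_ratio:.3g} "
            f"[{self.ci_low:.3g}, {self.ci_high:.3g}] "
            f"(O/E A: {self.observed_a:.0f}/{self.expected_a:.2f}, "
            f"B: {self.observed_b:.0f}/{self.expected_b:.2f})"
        )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogrankResult:
    """Mantel-Cox log-rank over the pooled event times.

    At each distinct event time the 2x2 table of (group x event) with
    hypergeometric variance contributes observed-minus-expected for
    group A; chi-square is ``(O_A - E_A)^2 / V``.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    rows = []
    o_a = e_a = o_b = e_b = var = 0.0
    for t in event_times:
        na = float(np.sum(ta >= t))
        nb = float(np.sum(tb >= t))
        n = na + nb
        da = float(np.sum((ta == t) & (ea == 1)))
        db = float(np.sum((tb == t) & (eb == 1)))
        d = da + db
        if n <= 0 or d == 0:
            continue
        exp_a = d * na / n
        exp_b = d * nb / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_a += da
        o_b += db
        e_a += exp_a
        e_b += exp_b
        var += v
        rows.append(
            {"time": t, "at_risk_a": na, "at_risk_b": nb, "events_a": da,
             "events_b": db, "expected_a": exp_a, "variance": v}
        )
    table = pd.DataFrame(rows)

    if var > 0:
        chi2 = (o_a - e_a) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0

    if e_a > 0 and e_b > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
    elif o_a == 0:
        hr = 0.0
    else:
        hr = float("inf")
    if hr in (0.0, float("inf")) or e_a == 0 or e_b == 0:
        ci_low, ci_high = float("nan"), float("nan")
    else:
        se = np.sqrt(1.0 / e_a + 1.0 / e_b)
        ci_low = float(hr * np.exp(-1.96 * se))
        ci_high = float(hr * np.exp(1.96 * se))
    return LogrankResult(
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=float(hr),
        ci_low=ci_low,
        ci_high=ci_high,
        observed_a=o_a,
        expected_a=e_a,
        observed_b=o_b,
        expected_b=e_b,
        table=table,
    )


@dataclass
class StratifiedOutcomes:
    """Per-stratum Kaplan-Meier summaries plus pairwise log-rank tests."""

    strata: pd.DataFrame  # index stratum; n, events, median
    pairwise: pd.DataFrame  # numerator, denominator, hr, ci_low, ci_high, chi2, p
    km: dict

    def summary(self) -> str:
        out = ["Per-stratum outcomes:", self.strata.to_string()]
        if not self.pairwise.empty:
            out += ["Pairwise Mantel-Cox log-rank (HR numerator listed first):",
                    self.pairwise.to_string(index=False)]
        return "\n".join(out)


def stratified_outcomes(
    records: pd.DataFrame,
    stratifier: str,
    *,
    time_col: str = "time_months",
    event_col: str = "event",
    within: Optional[dict] = None,
) -> StratifiedOutcomes:
    """KM medians and all pairwise log-rank comparisons across strata.

    ``within`` filters rows first (e.g. ``{"tki_generation": "2nd"}``),
    supporting both group-vs-group-within-drug-class and
    class-vs-class-within-group layouts.  Rows with a missing stratum
    label fall into an explicit ``"other"`` stratum; strata without
    events are skipped with a warning.  The HR numerator arm is stated
    explicitly per comparison.
    """
    df = records.copy()
    if within:
        for col, val in within.items():
            df = df[df[col] == val]
    if df.empty:
        raise ValueError("no records after filtering")
    df[stratifier] = df[stratifier].fillna("other")

    km: dict = {}
    rows = {}
    usable = []
    for stratum, sub in df.groupby(stratifier, sort=True):
        res = km_estimate(sub[time_col], sub[event_col])
        km[stratum] = res
        rows[stratum] = {"n": res.n, "events": res.n_events, "median": res.median}
        if res.n_events > 0:
            usable.append(stratum)
        else:
            warnings.warn(f"stratum {stratum!r} has no events; skipped in pairwise tests")
    strata = pd.DataFrame.from_dict(rows, orient="index")

    pairs = []
    for a, b in itertools.combinations(usable, 2):
        sa = df[df[stratifier] == a]
        sb = df[df[stratifier] == b]
        lr = logrank_test(sa[time_col], sa[event_col], sb[time_col], sb[event_col])
        pairs.append(
            {"numerator": a, "denominator": b, "hr": lr.hazard_ratio,
             "ci_low": lr.ci_low, "ci_high": lr.ci_high,
             "chi_square": lr.chi_square, "p_value": lr.p_value}
        )
    pairwise = pd.DataFrame(
        pairs,
        columns=["numerator", "denominator", "hr", "ci_low", "ci_high", "chi_square", "p_value"],
    )
    return StratifiedOutcomes(strata, pairwise, km)


@dataclass
class OrrResult:
    """Per-group overall response rate with pairwise Fisher exact tests."""

    per_group: pd.DataFrame  # index group; n_evaluable, responders, orr
    pairwise: pd.DataFrame  # group_a, group_b, odds_ratio, p_value

    def summary(self) -> str:
        return "\n".join(
            ["ORR by group:", self.per_group.to_string(),
             "Pairwise Fisher exact (two-sided):", self.pairwise.to_string(index=False)]
        )


def orr_analysis(
    responses: pd.DataFrame,
    *,
    group_col: str = "group",
    response_col: str = "best_response",
) -> OrrResult:
    """ORR = (CR + PR) / evaluable per group; two-sided Fisher exact
    tests on all pairwise responder/non-responder 2x2 tables.

    Not-evaluable (NE) records are excluded from the denominator; groups
    with zero evaluable patients are dropped with a warning.
    """
    df = responses.copy()
    bad = set(df[response_col]) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    df = df[df[response_col] != "NE"]

    rows = {}
    for group, sub in df.groupby(group_col, sort=True):
        n = len(sub)
        resp = int(sub[response_col].isin(["CR", "PR"]).sum())
        rows[group] = {"n_evaluable": n, "responders": resp, "orr": resp / n}
    all_groups = responses[group_col].unique()
    empty = [g for g in all_groups if g not in rows]
    if empty:
        warnings.warn(f"groups with zero evaluable patients excluded: {empty}")
    if len(rows) < 2:
        raise ValueError("need >=2 groups with evaluable patients")
    per_group = pd.DataFrame.from_dict(rows, orient="index")

    pairs = []
    names = sorted(rows, key=str)
    for a, b in itertools.combinations(names, 2):
        ra, na = rows[a]["responders"], rows[a]["n_evaluable"]
        rb, nb = rows[b]["responders"], rows[b]["n_evaluable"]
        table = [[ra, na - ra], [rb, nb - rb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        pairs.append({"group_a": a, "group_b": b, "odds_ratio": float(odds), "p_value": float(p)})
    return OrrResult(per_group, pd.DataFrame(pairs))
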