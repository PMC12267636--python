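"""Kaplan-Meier lifespan statistics.

Product-limit estimation with Greenwood variance, linear interpolation of
the median between the two step points nearest 50% survival, the
100-replicate bootstrap median/standard-error procedure, two-sided log-rank
tests, and the percent-change / suppression arithmetic used to summarize
lifespan experiments.  Censored individuals at an event time remain at risk
for the events at that time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class SurvivalSample:
    """Censored event times (days) for one condition."""

    times: np.ndarray
    events: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if (self.times <= 0).any():
            raise ValueError("times must be > 0")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("events must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SurvivalConfig:
    n_bootstrap: int = 100
    seed: int = 0
    median_level: float = 0.5

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit survival estimate with Greenwood variance.

    Attributes (after ``fit``)
    --------------------------
    event_times_ : ndarray
        Distinct event (death) times.
    survival_ : ndarray
        S(t) immediately after each event time (non-increasing, starts from
        1 before the first event).
    at_risk_ : ndarray
        Number at risk just before each event time.
    n_events_ : ndarray
    greenwood_var_ : ndarray
    median_ : float
        Interpolated median survival (NaN when S never reaches 0.5).
    median_defined_ : bool
    """

    def __init__(self, median_level: float = 0.5):
        self.median_level = median_level

    def fit(self, times: Sequence[float], events: Sequence[int], y=None):
        s = SurvivalSample(np.asarray(times), np.asarray(events))
        if s.events.sum() < 1:
            warnings.warn("all observations censored; survival stays at 1")
        order = np.argsort(s.times, kind="stable")
        t, e = s.times[order], s.events[order]
        ut = np.unique(t[e == 1])
        n = t.size
        at_risk = np.array([(t >= v).sum() for v in ut], dtype=float)
        d = np.array([((t == v) & (e == 1)).sum() for v in ut], dtype=float)
        surv = np.cumprod(1.0 - d / at_risk)
        # Greenwood terms; undefined (NaN) once survival reaches zero
        finite = at_risk > d
        gw_terms = np.where(finite, d / (at_risk * np.maximum(at_risk - d, 1)), 0.0)
        gw_var = surv**2 * np.cumsum(gw_terms)
        gw_var[~np.logical_and.accumulate(finite)] = np.nan
        self.event_times_ = ut
        self.survival_ = surv
        self.at_risk_ = at_risk.astype(int)
        self.n_events_ = d.astype(int)
        self.greenwood_var_ = gw_var
        self.median_ = interpolated_median(
            ut, surv, level=self.median_level
        )
        self.median_defined_ = bool(np.isfinite(self.median_))
        return self

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.event_times_, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times_,
                "survival": self.survival_,
                "at_risk": self.at_risk_,
                "events": self.n_events_,
                "greenwood_var": self.greenwood_var_,
            }
        )


def km_fit(s: SurvivalSample) -> KaplanMeierEstimator:
    """Fit the product-limit estimator to one condition's sample."""
    return KaplanMeierEstimator().fit(s.times, s.events)


def interpolated_median(
    step_times: np.ndarray, survival: np.ndarray, level: float = 0.5
) -> float:
    """Median survival by linear interpolation between the two step points
    nearest the target level.

    With (t1, S1) the last step above the level and (t2, S2) the first at or
    below it: ``median = t1 + (S1 - level)/(S1 - S2) * (t2 - t1)``.  A step
    landing exactly on the level returns that step's time.  The curve starts
    from (0, 1).  Returns NaN when survival never reaches the level.
    """
    t = np.asarray(step_times, dtype=float)
    s = np.asarray(survival, dtype=float)
    below = np.flatnonzero(s <= level)
    if below.size == 0:
        return float("nan")
    i = below[0]
    t2, s2 = t[i], s[i]
    if s2 == level or i == 0:
        # lands exactly on the level, or the very first step already
        # crosses it (no earlier step time to interpolate from)
        return float(t2)
    t1, s1 = t[i - 1], s[i - 1]
    return float(t1 + (s1 - level) / (s1 - s2) * (t2 - t1))


def bootstrap_median(
    s: SurvivalSample, cfg: Optional[SurvivalConfig] = None
) -> Tuple[float, float, Dict[str, float]]:
    """Bootstrap distribution of the interpolated KM median.

    Individuals (time, event) are resampled with replacement ``n_bootstrap``
    times; each replicate is refit and its interpolated median recorded.
    The point estimate is the median of the replicate medians and the
    standard error their standard deviation.  Replicates whose survival
    never reaches 50% are dropped (counted in the info dict); more than half
    undefined is an error.
    """
    cfg = cfg or SurvivalConfig()
    if len(s) < 10:
        warnings.warn("sample size < 10; bootstrap medians will be unstable")
    rng = np.random.default_rng(cfg.seed)
    n = len(s)
    medians = []
    undefined = 0
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        est = KaplanMeierEstimator(median_level=cfg.median_level).fit(
            s.times[idx], s.events[idx]
        )
        if est.median_defined_:
            medians.append(est.median_)
        else:
            undefined += 1
    if undefined > cfg.n_bootstrap / 2:
        raise ValueError(
            f"{undefined}/{cfg.n_bootstrap} bootstrap replicates have an "
            "undefined median"
        )
    med = np.asarray(medians)
    point = float(np.median(med))
    se = float(np.std(med, ddof=1)) if med.size > 1 else 0.0
    info = {
        "n_replicates": cfg.n_bootstrap,
        "n_undefined": undefined,
        "full_data_median": KaplanMeierEstimator().fit(s.times, s.events).median_,
    }
    return point, se, info


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> Tuple[float, float]:
    """Two-sided log-rank test; returns (chi-square, p) with 1 df.

    Observed-minus-expected statistic over pooled event times with the
    hypergeometric variance.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a.events.sum() + b.events.sum() < 1:
        raise ValueError("need >= 1 event overall")
    ut = np.unique(np.concatenate([a.times[a.events == 1], b.times[b.events == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in ut:
        n1 = float((a.times >= t).sum())
        n2 = float((b.times >= t).sum())
        d1 = float(((a.times == t) & (a.events == 1)).sum())
        d2 = float(((b.times == t) & (b.events == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n <= 1:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def percent_median_change(treated_median: float, control_median: float) -> float:
    """100 x (treated - control)/control, to one decimal."""
    if control_median <= 0:
        raise ValueError("control median must be > 0")
    return round(100.0 * (treated_median - control_median) / control_median, 1)


def suppression_percent(
    reduction_ref: float, reduction_mut: float
) -> Tuple[int, bool]:
    """How much of a reference lifespan reduction a mutant suppresses.

    ``100 x (reduction_ref - reduction_mut)/reduction_ref``, rounded to the
    nearest integer.  Returns (value, warning_flag); the flag is set for
    sign-discordant reductions.
    """
    if reduction_ref == 0:
        raise ValueError("reference reduction must be non-zero")
    flag = reduction_ref * reduction_mut < 0
    if flag:
        warnings.warn("sign-discordant reductions; suppression value is suspect")
    value = 100.0 * (reduction_ref - reduction_mut) / reduction_ref
    return int(round(value)), flag


def survival_summary(
    data: pd.DataFrame,
    control: str,
    cfg: Optional[SurvivalConfig] = None,
) -> pd.DataFrame:
    """Per-group results table: n, bootstrap median, SE, percent change vs
    control, log-rank p vs control.

    ``data`` holds columns time, event, group.
    """
    cfg = cfg or SurvivalConfig()
    groups = {
        g: SurvivalSample(grp["time"].to_numpy(), grp["event"].to_numpy(), g)
        for g, grp in data.groupby("group", sort=True)
    }
    if control not in groups:
        raise ValueError(f"control group {control!r} absent from the data")
    ctrl = groups[control]
    ctrl_med, _, _ = bootstrap_median(ctrl, cfg)
    rows = []
    for g in sorted(groups):
        s = groups[g]
        med, se, info = bootstrap_median(s, cfg)
        row = {
            "group": g,
            "n": len(s),
            "median": med,
            "se": se,
            "full_data_median": info["full_data_median"],
        }
        if g != control:
            chi2, p = logrank_test(s, ctrl)
            row["pct_change_vs_control"] = percent_median_change(med, ctrl_med)
            row["logrank_p_vs_control"] = p
        else:
            row["pct_change_vs_control"] = 0.0
            row["logrank_p_vs_control"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
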