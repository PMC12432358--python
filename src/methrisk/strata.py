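"""Survival stratification of a dichotomized risk score.

Predicted risks are split at a cutoff (strictly greater than goes to the
high group; the boundary stays low), and group separation is quantified by
Kaplan-Meier curves, the two-group log-rank test (unweighted), and a
single-covariate weighted Cox hazard ratio with its Wald 95% CI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import weighted_cox_fit
from .ipw import KmEstimate, km_estimator

__all__ = ["StrataResult", "dichotomize", "logrank_test", "strata_hazard_ratio",
           "stratify_and_test"]


@dataclass
class StrataResult:
    n_low: int
    n_high: int
    km_low: KmEstimate
    km_high: KmEstimate
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci95: tuple
    hr_p: float

    def as_dict(self) -> dict:
        return {"n_low": self.n_low, "n_high": self.n_high,
                "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
                "hr": self.hr, "hr_ci95": list(self.hr_ci95), "hr_p": self.hr_p}

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def dichotomize(predicted_risk, cutoff: float) -> np.ndarray:
    """Group labels 'high' iff predicted_risk > cutoff (boundary goes low)."""
    risk = np.asarray(predicted_risk, dtype=float)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return np.where(risk > cutoff, "high", "low")


def logrank_test(times, events, groups) -> tuple:
    """Two-group log-rank test; returns (chi2, p) with 1 df.

    At each distinct event time, the observed events in group 1 are
    compared with their expectation under the pooled hazard; the variance
    is hypergeometric.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, got {len(labels)}")
    g1 = groups == labels[1]
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def strata_hazard_ratio(times, events, group_indicator, weights=None) -> tuple:
    """Weighted Cox HR of high vs low group: (hr, (lo, hi), p).

    `group_indicator` is 1 for the high group. If one group has no events
    the likelihood is monotone; the point estimate is reported as inf/0
    with a one-sided bound from the separation-flagged fit.
    """
    x = np.asarray(group_indicator, dtype=float)[:, None]
    fit = weighted_cox_fit(x, times, events, weights)
    hr = float(np.exp(fit.coef[0]))
    lo, hi = fit.ci95()[0]
    if not fit.converged:
        events_arr = np.asarray(events, dtype=int)
        high = x[:, 0] == 1
        if events_arr[high].sum() == 0:
            return 0.0, (0.0, float(hi)), float("nan")
        if events_arr[~high].sum() == 0:
            return float("inf"), (float(lo), float("inf")), float("nan")
    return hr, (float(lo), float(hi)), float(fit.p[0])


def stratify_and_test(times, events, predicted_risk, cutoff: float,
                      weights=None) -> StrataResult:
    """Full stratification report: KM per stratum, log-rank, weighted-Cox HR."""
    labels = dichotomize(predicted_risk, cutoff)
    high = labels == "high"
    if high.all() or (~high).all():
        raise ValueError("cutoff places every subject in one group")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    km_low = km_estimator(times[~high], events[~high])
    km_high = km_estimator(times[high], events[high])
    chi2, p = logrank_test(times, events, labels)
    hr, ci, hr_p = strata_hazard_ratio(times, events, high.astype(int), weights)
    return StrataResult(n_low=int((~high).sum()), n_high=int(high.sum()),
                        km_low=km_low, km_high=km_high,
                        logrank_chi2=chi2, logrank_p=p,
                        hr=hr, hr_ci95=ci, hr_p=hr_p)
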