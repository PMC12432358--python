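"""Weighted Cox proportional-hazards fitting by Newton-Raphson.

The partial likelihood uses Breslow's approximation for tied event times,
which stays exact under case weights: a subject with integer weight w
contributes identically to w duplicated subjects. Ties between an event
and a censoring at the same time follow the conventional rule (the event
precedes the censoring, i.e. censored subjects remain in the risk set at
their own time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "weighted_cox_fit"]

MAX_ABS_COEF = 20.0  # beyond this the likelihood is effectively monotone (separation)


@dataclass
class CoxFit:
    """Result of a weighted Cox partial-likelihood fit."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci95(self) -> np.ndarray:
        """95% Wald CI for the hazard ratios, shape (p, 2)."""
        z = stats.norm.ppf(0.975)
        with np.errstate(over="ignore"):
            return np.column_stack([np.exp(self.coef - z * self.se),
                                    np.exp(self.coef + z * self.se)])


def _event_groups(t_sorted, e_sorted, w_sorted, x_sorted):
    """Tied-event-time groups over the descending-time ordering.

    For each distinct time carrying at least one event, returns
    (last_risk_index, weighted event count d, weighted event covariate sum).
    `last_risk_index` is the last position whose subject is still at risk at
    that time, i.e. the cumulative sums up to it cover the Breslow risk set.
    """
    n = len(t_sorted)
    groups = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        ev = e_sorted[i:j + 1] == 1
        if ev.any():
            d = float(np.sum(w_sorted[i:j + 1][ev]))
            wx = (w_sorted[i:j + 1][ev, None] * x_sorted[i:j + 1][ev]).sum(axis=0)
            groups.append((j, d, wx))
        i = j + 1
    return groups


def weighted_cox_fit(covariates, times, events, weights=None,
                     tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Fit a weighted Cox model, returning coefficients, SEs and Wald p-values.

    Parameters
    ----------
    covariates : (n, p) array of numeric covariates (no constant column).
    times, events : observed follow-up times (> 0) and 0/1 event indicators.
    weights : optional positive per-subject case weights (default all 1).
    tol : convergence when the max absolute score falls below this.
    max_iter : Newton iteration cap; non-convergence or a coefficient
        escaping past +-20 (separation) is reported via ``converged=False``
        rather than raised, so genome-wide scans can carry flagged rows.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = x.shape
    if n != len(times) or n != len(events):
        raise ValueError("covariates, times and events must have matching length")
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant covariate column")

    order = np.argsort(-times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    w_sorted, x_sorted = w[order], x[order]
    groups = _event_groups(t_sorted, e_sorted, w_sorted, x_sorted)

    def parts(beta, want_derivs=True):
        eta = x_sorted @ beta
        shift = eta.max()
        r = w_sorted * np.exp(eta - shift)
        s0 = np.cumsum(r)
        s1 = np.cumsum(r[:, None] * x_sorted, axis=0)
        rx = r[:, None] * x_sorted
        loglik = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        s2 = np.zeros((p, p))
        last = -1
        for gi, d, wx in groups:
            if want_derivs and gi > last:
                seg = slice(last + 1, gi + 1)
                s2 = s2 + x_sorted[seg].T @ rx[seg]
                last = gi
            S0 = s0[gi]
            loglik += float(wx @ beta) - d * (np.log(S0) + shift)
            if want_derivs:
                S1 = s1[gi]
                grad += wx - d * S1 / S0
                info += d * (s2 / S0 - np.outer(S1, S1) / S0**2)
        return loglik, grad, info

    beta = np.zeros(p)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loglik, grad, info = parts(beta)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        for _ in range(25):  # step-halving keeps the likelihood monotone
            if parts(new_beta, want_derivs=False)[0] >= loglik - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta = new_beta
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            break

    loglik, grad, info = parts(beta)
    converged = bool(np.max(np.abs(grad)) < tol and np.max(np.abs(beta)) <= MAX_ABS_COEF)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return CoxFit(coef=beta, se=se, p=pvals, log_partial_likelihood=float(loglik),
                  converged=converged, n_iter=n_iter)
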