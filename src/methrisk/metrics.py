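"""Discrimination, screening and reclassification metrics.

ROC curves are empirical step functions over all distinct prediction
thresholds with AUC by the trapezoid rule (equal to the Mann-Whitney
U-statistic probability for unweighted data). Paired AUCs are compared
with DeLong's test. The Youden index J = sensitivity + specificity - 1
picks the screening cutoff, and predictive values at a given prevalence
follow Bayes' rule. NRI/IDI quantify the added value of a new risk model
over a base model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["RocCurve", "ScreeningReport", "ReclassificationReport",
           "roc_curve", "pr_curve", "compare_auc", "youden_cutoff",
           "screening_metrics", "nri_idi"]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_two_class(outcome):
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    return y


def roc_curve(predicted, outcome, weights=None) -> RocCurve:
    """Empirical ROC over all distinct thresholds; AUC by trapezoid.

    A point is called positive when predicted > threshold. With weights,
    both axes use weighted counts.
    """
    y = _check_two_class(outcome)
    s = np.asarray(predicted, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y, w = s[order], y[order], w[order]
    # collapse tied scores
    distinct = np.r_[np.where(np.diff(s) != 0)[0], len(s) - 1]
    tp = np.cumsum(w * y)[distinct]
    fp = np.cumsum(w * (1 - y))[distinct]
    P, N = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def pr_curve(predicted, outcome, weights=None):
    """Precision-recall pairs over the same distinct thresholds as the ROC."""
    y = _check_two_class(outcome)
    s = np.asarray(predicted, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y, w = s[order], y[order], w[order]
    distinct = np.r_[np.where(np.diff(s) != 0)[0], len(s) - 1]
    tp = np.cumsum(w * y)[distinct]
    pred_pos = np.cumsum(w)[distinct]
    recall = tp / tp[-1]
    precision = tp / pred_pos
    return recall, precision


def _midrank(x):
    """Midranks as used by DeLong's fast algorithm."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        ranks[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.zeros(n)
    out[order] = ranks
    return out


def _delong_components(preds, outcome):
    """AUCs and the DeLong covariance matrix for k paired score vectors."""
    y = np.asarray(outcome, dtype=int)
    pos = [p[y == 1] for p in preds]
    neg = [p[y == 0] for p in preds]
    m, n = len(pos[0]), len(neg[0])
    k = len(preds)
    v10 = np.zeros((k, m))
    v01 = np.zeros((k, n))
    aucs = np.zeros(k)
    for r in range(k):
        allv = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(allv)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10[0], ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01[0], ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def compare_auc(pred_a, pred_b, outcome) -> float:
    """DeLong's test for two paired ROC curves; returns the two-sided p.

    Identical prediction vectors (zero AUC difference with zero variance)
    return p = 1.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = _check_two_class(outcome)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired predictions must share the samples and outcome")
    aucs, cov = _delong_components([a, b], y)
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def youden_cutoff(roc: RocCurve):
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the lower cutoff. Returns
    (cutoff, sensitivity, specificity); a warning is logged when even the
    best J is <= 0 (anti-predictive scores).
    """
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC")
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last max = lowest cutoff
    cutoff = float(roc.thresholds[best])
    if j[best] <= 0:
        logger.warning("Youden index <= 0: scores are not predictive in this direction")
    return cutoff, float(roc.tpr[best]), float(1.0 - roc.fpr[best])


@dataclass
class ScreeningReport:
    """Confusion counts and prevalence-based predictive values for a cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int
    prevalence: float
    ppv: float
    npv: float
    accuracy: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def screening_metrics(sensitivity: float, specificity: float,
                      n_events: int, n_controls: int,
                      cutoff: float = np.nan) -> ScreeningReport:
    """Screening-test report from sensitivity/specificity and group sizes.

    Confusion counts are rounded half-away-from-zero. PPV/NPV/accuracy come
    from Bayes' rule at the prevalence n_events / (n_events + n_controls)
    quoted at screening-report precision (one decimal of a percent), the
    convention under which such summary diagrams are printed.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_events <= 0 or n_controls <= 0:
        raise ValueError("counts must be positive")
    prev_exact = n_events / (n_events + n_controls)
    prev = round(prev_exact, 3)
    tp = _round_half_away(sensitivity * n_events)
    tn = _round_half_away(specificity * n_controls)
    fn = n_events - tp
    fp = n_controls - tn
    denom_p = sensitivity * prev + (1 - specificity) * (1 - prev)
    denom_n = specificity * (1 - prev) + (1 - sensitivity) * prev
    ppv = sensitivity * prev / denom_p if denom_p > 0 else np.nan
    npv = specificity * (1 - prev) / denom_n if denom_n > 0 else np.nan
    accuracy = sensitivity * prev + specificity * (1 - prev)
    return ScreeningReport(cutoff=cutoff, sensitivity=sensitivity,
                           specificity=specificity, tp=tp, fn=fn, tn=tn, fp=fp,
                           prevalence=prev, ppv=ppv, npv=npv, accuracy=accuracy)


@dataclass
class ReclassificationReport:
    """NRI/IDI for a new risk model against a base model."""

    nri_categorical: float
    nri_categorical_ci95: tuple
    nri_categorical_p: float
    nri_continuous: float
    nri_continuous_ci95: tuple
    nri_continuous_p: float
    idi: float
    idi_ci95: tuple
    idi_p: float
    nri_events: float
    nri_nonevents: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _nri_half(up, down, n):
    """Per-group NRI component with its variance: (p_up - p_down, var)."""
    p_up, p_down = up / n, down / n
    return p_up - p_down, (p_up + p_down - (p_up - p_down) ** 2) / n


def nri_idi(pred_base, pred_new, outcome, category_cutoff: float) -> ReclassificationReport:
    """Categorical and continuous NRI plus IDI, with Wald CIs and p-values.

    Two risk categories split at `category_cutoff` define up/down moves for
    the categorical NRI; any increase/decrease in predicted risk counts for
    the continuous NRI. IDI is the difference of discrimination slopes.
    """
    base = np.asarray(pred_base, dtype=float)
    new = np.asarray(pred_new, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if len(base) != len(new) or len(base) != len(y):
        raise ValueError("predictions and outcome must align")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both events and non-events are required")
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    z975 = stats.norm.ppf(0.975)

    def assemble(up_e, down_e, up_ne, down_ne):
        nri_e, var_e = _nri_half(up_e, down_e, n_e)
        nri_ne, var_ne = _nri_half(down_ne, up_ne, n_ne)  # down-moves help non-events
        nri = nri_e + nri_ne
        se = math.sqrt(var_e + var_ne)
        ci = (nri - z975 * se, nri + z975 * se)
        p = 2.0 * stats.norm.sf(abs(nri) / se) if se > 0 else 1.0
        return nri, ci, float(p), nri_e, nri_ne

    cat_base = base > category_cutoff
    cat_new = new > category_cutoff
    up = cat_new & ~cat_base
    down = ~cat_new & cat_base
    nri_c, ci_c, p_c, nri_e_c, nri_ne_c = assemble(
        up[ev].sum(), down[ev].sum(), up[ne].sum(), down[ne].sum())

    up2 = new > base
    down2 = new < base
    nri_k, ci_k, p_k, _, _ = assemble(
        up2[ev].sum(), down2[ev].sum(), up2[ne].sum(), down2[ne].sum())

    d = new - base
    idi = float(d[ev].mean() - d[ne].mean())
    se_idi = math.sqrt(d[ev].var(ddof=1) / n_e + d[ne].var(ddof=1) / n_ne) \
        if n_e > 1 and n_ne > 1 else 0.0
    ci_idi = (idi - z975 * se_idi, idi + z975 * se_idi)
    p_idi = float(2.0 * stats.norm.sf(abs(idi) / se_idi)) if se_idi > 0 else 1.0

    return ReclassificationReport(
        nri_categorical=nri_c, nri_categorical_ci95=ci_c, nri_categorical_p=p_c,
        nri_continuous=nri_k, nri_continuous_ci95=ci_k, nri_continuous_p=p_k,
        idi=idi, idi_ci95=ci_idi, idi_p=p_idi,
        nri_events=nri_e_c, nri_nonevents=nri_ne_c)
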