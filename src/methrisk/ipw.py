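"""Inverse-probability weights: sampling weights, Kaplan-Meier-based
censoring weights, and their product.

Sampling weights (w_samp) undo outcome-dependent sampling from a source
cohort: each case is weighted by cohort_cases / sampled_cases and each
control by cohort_controls / sampled_controls, so the weighted sample
represents the full cohort.

Censoring weights (w_cens) implement inverse probability of censoring
weighting (IPCW) for a fixed-horizon binary endpoint: let G(t) be the
Kaplan-Meier probability of remaining *uncensored* at t (censoring treated
as the event of interest; administrative end-of-study does not count as
censoring). A subject observed to the event, or event-free to the horizon,
is up-weighted by 1/G evaluated at the left limit of their own time; a
subject censored event-free before the horizon contributes weight 0 — its
mass is redistributed to those still at risk.

Cox-stage consumers receive w_samp only (censoring is handled by the Cox
likelihood itself); logistic-stage consumers receive w_final =
w_samp * w_cens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["KmEstimate", "WeightSet", "sampling_weights", "km_estimator",
           "censoring_weights", "combine_weights"]


@dataclass
class KmEstimate:
    """Product-limit survival estimate: S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""

    times: np.ndarray      # distinct event times, increasing
    survival: np.ndarray   # S(t_i), non-increasing
    at_risk: np.ndarray    # (weighted) number at risk just before t_i
    events: np.ndarray     # (weighted) events at t_i

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or (len(self.survival) and self.survival[0] > 1 + 1e-12):
            raise ValueError("survival must be non-increasing and <= 1")

    def _eval(self, t, side) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side=side) - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def at(self, t) -> np.ndarray:
        """Evaluate the right-continuous step function S(t)."""
        return self._eval(t, "right")

    def at_left(self, t) -> np.ndarray:
        """Left limit S(t-): the survival just before t."""
        return self._eval(t, "left")


@dataclass
class WeightSet:
    """Per-sample sampling weights, censoring weights, and their product."""

    sample_ids: list
    w_samp: np.ndarray
    w_cens: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.w_samp = np.asarray(self.w_samp, dtype=float)
        self.w_cens = np.asarray(self.w_cens, dtype=float)
        if len(self.sample_ids) != len(self.w_samp) or len(self.w_samp) != len(self.w_cens):
            raise ValueError("sample_ids, w_samp and w_cens lengths differ")
        if (self.w_samp <= 0).any():
            raise ValueError("sampling weights must be positive")
        if (self.w_cens < 0).any():
            raise ValueError("censoring weights must be non-negative")

    @property
    def w_final(self) -> np.ndarray:
        return self.w_samp * self.w_cens

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "w_samp": self.w_samp,
                             "w_cens": self.w_cens, "w_final": self.w_final})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def sampling_weights(cohort_counts: dict, sample_counts: dict,
                     phenotypes: PhenotypeTable) -> np.ndarray:
    """Inverse-probability-of-sampling weights per subject.

    Each stratum (cases = event 1, controls = event 0) gets
    cohort_count / sample_count.
    """
    for key in ("cases", "controls"):
        if key not in cohort_counts or key not in sample_counts:
            raise ValueError(f"counts must contain {key!r}")
        if sample_counts[key] == 0:
            raise ZeroDivisionError(f"zero sampled {key}")
        if sample_counts[key] > cohort_counts[key]:
            raise ValueError(f"sampled {key} exceed cohort {key}")
    n_cases = int(phenotypes.event.sum())
    n_controls = phenotypes.n_samples - n_cases
    if (n_cases, n_controls) != (sample_counts["cases"], sample_counts["controls"]):
        raise ValueError(
            f"sample_counts {sample_counts} do not match phenotype table "
            f"(cases={n_cases}, controls={n_controls})")
    w_case = cohort_counts["cases"] / sample_counts["cases"]
    w_ctrl = cohort_counts["controls"] / sample_counts["controls"]
    return np.where(phenotypes.event == 1, w_case, w_ctrl).astype(float)


def km_estimator(times, event_indicator, weights=None) -> KmEstimate:
    """Weighted Kaplan-Meier product-limit estimate.

    The caller chooses what counts as the "event": pass the censoring
    indicator to estimate the probability of remaining uncensored. At tied
    times, events are removed from the risk set only after the tie is
    processed (events precede censorings).
    """
    times = np.asarray(times, dtype=float)
    ind = np.asarray(event_indicator, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if weights is None:
        weights = np.ones(len(times))
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    order = np.argsort(times, kind="stable")
    t, e, ww = times[order], ind[order], w[order]
    uniq, start = np.unique(t, return_index=True)
    total = ww.sum()
    # weighted count leaving the risk set strictly before each distinct time
    removed_before = np.concatenate([[0.0], np.cumsum(np.add.reduceat(ww, start))[:-1]])
    at_risk = total - removed_before
    d = np.add.reduceat(np.where(e == 1, ww, 0.0), start)
    keep = d > 0
    surv = np.cumprod(1.0 - d / at_risk)
    return KmEstimate(times=uniq[keep], survival=surv[keep],
                      at_risk=at_risk[keep], events=d[keep])


def censoring_weights(times, event_indicator, horizon: float,
                      g_floor: float = 0.05,
                      keep_early_censored: bool = False) -> np.ndarray:
    """IPCW weights for a fixed-horizon binary endpoint.

    Parameters
    ----------
    times, event_indicator : observed follow-up and 0/1 event status.
    horizon : administrative end of study in years; event-free follow-up
        reaching the horizon is complete, not censored.
    g_floor : lower clip on the uncensored-probability G to cap weights
        (default 0.05, i.e. weights capped at 20).
    keep_early_censored : if True, subjects censored event-free before the
        horizon keep weight 1/G(their time-) instead of 0 (the alternative
        reading under which all subjects enter the logistic models).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_indicator, dtype=int)
    # censoring as the event of interest; reaching the horizon is not censoring
    cens = ((events == 0) & (times < horizon)).astype(int)
    if cens.sum() > 0:
        g = km_estimator(times, cens)
    else:
        g = None

    def g_at_left(t):
        if g is None:
            return np.ones_like(np.asarray(t, dtype=float))
        return np.asarray(g.at_left(t), dtype=float)

    w = np.zeros(len(times))
    complete = (events == 1) | (times >= horizon)
    eval_t = np.where(events == 1, times, np.minimum(times, horizon))
    gv = g_at_left(eval_t)
    clipped = int(np.sum(gv[complete] < g_floor))
    if clipped:
        logger.warning("censoring weights: G clipped at floor %.3g for %d subjects",
                       g_floor, clipped)
    gv = np.clip(gv, g_floor, None)
    w[complete] = 1.0 / gv[complete]
    if keep_early_censored:
        early = ~complete
        w[early] = 1.0 / np.clip(g_at_left(times[early]), g_floor, None)
    return w


def combine_weights(sample_ids, w_samp, w_cens) -> WeightSet:
    """Elementwise product of sampling and censoring weights as a WeightSet."""
    sample_ids = list(sample_ids)
    w_samp = np.asarray(w_samp, dtype=float)
    w_cens = np.asarray(w_cens, dtype=float)
    if len(sample_ids) != len(w_samp) or len(w_samp) != len(w_cens):
        raise ValueError("mismatched sample sets for weight combination")
    return WeightSet(sample_ids=sample_ids, w_samp=w_samp, w_cens=w_cens)
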