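"""Per-site weighted Cox EWAS, multiple-testing correction, robustness
screening and effect-size filtering, plus the lightweight tissue-relevance
statistics (paired t-tests and Spearman methylation-expression correlation).

Each CpG site enters its own Cox model as the M-value standardized to unit
SD, so hazard ratios read "per 1 SD increase in methylation". Group means
and the delta-beta (events minus controls) are reported on the beta scale.
The scan is weighted by the sampling weights only; censoring is handled by
the Cox likelihood itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import weighted_cox_fit
from .data import MethylationMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["CovariateModelSpec", "EwasSiteResult", "bh_fdr", "ewas_scan",
           "robustness_screen", "delta_beta_filter", "paired_ttest_fdr",
           "spearman_assoc", "results_to_frame", "write_results",
           "MODEL_1_COVARIATES"]

# Primary discovery model: age, gender, BMI and HbA1c. Richer models add
# cell-composition estimates, medication flags, the smoking proxy and lipids
# as extra phenotype columns, configured by the caller.
MODEL_1_COVARIATES = ["age", "gender", "bmi", "hba1c"]


@dataclass
class CovariateModelSpec:
    """A numbered covariate adjustment set for the per-site Cox models."""

    model_id: int
    covariate_names: list

    @classmethod
    def model_1(cls) -> "CovariateModelSpec":
        return cls(1, list(MODEL_1_COVARIATES))


@dataclass
class EwasSiteResult:
    """Per-site association result from the weighted Cox scan."""

    site_id: str
    log_hr_per_sd: float
    se: float
    p: float
    q: float = np.nan
    mean_beta_events: float = np.nan
    mean_beta_controls: float = np.nan
    delta_beta: float = np.nan
    converged: bool = True
    p_by_model: dict = field(default_factory=dict)

    @property
    def hr_per_sd(self) -> float:
        return float(np.exp(self.log_hr_per_sd))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the
    input order. Never decreases any p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ewas_scan(matrix: MethylationMatrix, phenotypes: PhenotypeTable,
              model: CovariateModelSpec, weights=None) -> list:
    """Run the per-site weighted Cox scan under one covariate model.

    Returns one EwasSiteResult per site (original site order) with
    BH-FDR q-values computed over the scan. Sites whose fit fails
    (non-convergence/separation) are carried as flagged rows with p = 1.
    """
    if matrix.sample_ids != phenotypes.sample_ids:
        raise ValueError("matrix and phenotype sample IDs do not align")
    mvals = matrix.to_m().values
    betas = matrix.to_beta().values
    covs = phenotypes.covariate_matrix(model.covariate_names)
    times = phenotypes.time_years
    events = phenotypes.event
    is_event = events == 1
    if weights is None:
        weights = np.ones(phenotypes.n_samples)
    weights = np.asarray(weights, dtype=float)

    results = []
    for i, site_id in enumerate(matrix.site_ids):
        m = mvals[i]
        sd = m.std(ddof=1)
        mean_b_ev = float(betas[i][is_event].mean()) if is_event.any() else np.nan
        mean_b_ct = float(betas[i][~is_event].mean()) if (~is_event).any() else np.nan
        delta = mean_b_ev - mean_b_ct
        if sd == 0:
            results.append(EwasSiteResult(site_id, np.nan, np.nan, 1.0,
                                          mean_beta_events=mean_b_ev,
                                          mean_beta_controls=mean_b_ct,
                                          delta_beta=delta, converged=False))
            continue
        z = (m - m.mean()) / sd
        design = np.column_stack([z, covs])
        try:
            fit = weighted_cox_fit(design, times, events, weights)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("site %s: fit failed (%s)", site_id, exc)
            results.append(EwasSiteResult(site_id, np.nan, np.nan, 1.0,
                                          mean_beta_events=mean_b_ev,
                                          mean_beta_controls=mean_b_ct,
                                          delta_beta=delta, converged=False))
            continue
        p = fit.p[0] if np.isfinite(fit.p[0]) else 1.0
        results.append(EwasSiteResult(
            site_id=site_id, log_hr_per_sd=float(fit.coef[0]), se=float(fit.se[0]),
            p=float(p) if fit.converged else 1.0,
            mean_beta_events=mean_b_ev, mean_beta_controls=mean_b_ct,
            delta_beta=delta, converged=fit.converged))
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.p_by_model[model.model_id] = r.p
    return results


def robustness_screen(primary: list, secondary_scans: dict,
                      q_threshold: float = 0.05, p_threshold: float = 0.05) -> list:
    """Keep primary-model discoveries that replicate across secondary models.

    A site survives when q < q_threshold in the primary scan AND
    p < p_threshold in every supplied secondary scan. Per-model p-values are
    recorded on the surviving results.
    """
    surviving = []
    lookup = {mid: {r.site_id: r for r in scan} for mid, scan in secondary_scans.items()}
    for r in primary:
        if not r.q < q_threshold:
            continue
        keep = True
        for mid, sites in lookup.items():
            if r.site_id not in sites:
                raise ValueError(f"site {r.site_id!r} missing from secondary model {mid}")
            p_sec = sites[r.site_id].p
            r.p_by_model[mid] = p_sec
            if not p_sec < p_threshold:
                keep = False
        if keep:
            surviving.append(r)
    return surviving


def delta_beta_filter(results: list, threshold: float = 0.02) -> list:
    """Keep sites with |delta_beta| >= threshold (inclusive boundary).

    The default 2% absolute methylation difference between event and
    control groups selects sites large enough to be robust on the array.
    """
    return [r for r in results if abs(r.delta_beta) >= threshold]


def paired_ttest_fdr(matrix_a: MethylationMatrix, matrix_b: MethylationMatrix) -> pd.DataFrame:
    """Per-site paired t-test between two matrices with paired samples.

    Samples are paired by position after verifying identical sample ID
    lists; sites must match. Returns a DataFrame (site_id, t, p, q) with
    BH-FDR q-values. Zero-variance difference rows get t=0, p=1.
    """
    if matrix_a.site_ids != matrix_b.site_ids:
        raise ValueError("site lists differ between paired matrices")
    if sorted(matrix_a.sample_ids) != sorted(matrix_b.sample_ids):
        raise ValueError("sample pairing mismatch between matrices")
    b = matrix_b.subset_samples(matrix_a.sample_ids)
    n = matrix_a.n_samples
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = matrix_a.values - b.values
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame({"site_id": matrix_a.site_ids, "t": t, "p": p, "q": q})


def spearman_assoc(methylation_vector, expression_vector) -> tuple:
    """Spearman rank correlation (average ranks for ties) with t-approximation p."""
    x = np.asarray(methylation_vector, dtype=float)
    y = np.asarray(expression_vector, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need two equal-length vectors of length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def results_to_frame(results: list) -> pd.DataFrame:
    """Tabulate scan results; extra-model p-values become p_model<k> columns."""
    model_ids = sorted({mid for r in results for mid in r.p_by_model})
    rows = []
    for r in results:
        row = {"site_id": r.site_id, "log_hr_per_sd": r.log_hr_per_sd,
               "hr": r.hr_per_sd, "se": r.se, "p": r.p, "q": r.q,
               "mean_beta_events": r.mean_beta_events,
               "mean_beta_controls": r.mean_beta_controls,
               "delta_beta": r.delta_beta, "converged": r.converged}
        for mid in model_ids:
            if mid != min(model_ids):
                row[f"p_model{mid}"] = r.p_by_model.get(mid, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: list, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
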