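"""Methylation risk score construction and cross-validated risk prediction.

The MRS of a subject is the sum over selected CpG sites of the site's
standardized M-value times the site's effect size (the log hazard ratio
from the primary-model weighted Cox fit). Predicted event risks come from
weighted logistic regression (weights = sampling x censoring weights)
under stratified 5-fold cross-validation: folds are balanced on gender and
event status, each fold is predicted by a model trained on the others, and
the held-out predictions are pooled.

Two pipeline modes are provided. In "full" mode (default) site selection
and MRS coefficients come from the full-data EWAS and only the logistic
stage is cross-validated; "nested" mode refits the EWAS selection and
coefficients inside each training fold, giving an honest (leak-free)
generalization estimate at the cost of noisier selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import MethylationMatrix, PhenotypeTable
from .ewas import (CovariateModelSpec, delta_beta_filter, ewas_scan)
from .ipw import censoring_weights

logger = logging.getLogger(__name__)

__all__ = ["MrsModel", "RiskPrediction", "build_mrs", "score_mrs",
           "stratified_kfold", "cv_predict", "mrs_cv_pipeline",
           "CLINICAL_COVARIATES"]

# Clinical risk-factor adjustment set of the logistic prediction models.
CLINICAL_COVARIATES = ["age", "gender", "hba1c", "bmi", "smoking_proxy",
                       "med_diabetes", "med_lipid", "med_antihypertensive"]


@dataclass
class MrsModel:
    """Selected sites, their log-HR coefficients and standardization stats."""

    site_ids: list
    coefficients: np.ndarray         # log-HR per SD, one per site
    standardization: pd.DataFrame    # columns mean, sd indexed by site_id (M scale)

    def __post_init__(self):
        self.site_ids = list(self.site_ids)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site IDs in MRS model")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("MRS coefficients must be finite")


@dataclass
class RiskPrediction:
    """Pooled cross-validated predicted risks, one row per sample."""

    table: pd.DataFrame  # sample_id, fold_id, predicted_risk
    model_label: str

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            raise ValueError("each sample must appear exactly once")
        risks = self.table["predicted_risk"]
        if ((risks < 0) | (risks > 1)).any():
            raise ValueError("predicted risks must lie in [0, 1]")

    @property
    def predicted_risk(self) -> np.ndarray:
        return self.table["predicted_risk"].to_numpy()


def build_mrs(selected, matrix: MethylationMatrix) -> MrsModel:
    """MRS model from selected EWAS results plus the matrix that defines
    the per-site standardization (unweighted mean/SD of the M-values)."""
    site_ids = [r.site_id for r in selected]
    coefs = np.array([r.log_hr_per_sd for r in selected], dtype=float)
    missing = [s for s in site_ids if s not in set(matrix.site_ids)]
    if missing:
        raise ValueError(f"sites absent from matrix: {missing}")
    sub = matrix.to_m().subset_sites(site_ids)
    std = pd.DataFrame({"mean": sub.values.mean(axis=1),
                        "sd": sub.values.std(axis=1, ddof=1)},
                       index=pd.Index(site_ids, name="site_id"))
    return MrsModel(site_ids=site_ids, coefficients=coefs, standardization=std)


def score_mrs(model: MrsModel, matrix: MethylationMatrix) -> np.ndarray:
    """Per-sample MRS: sum_s coef_s * z_s where z is the standardized M-value."""
    missing = [s for s in model.site_ids if s not in set(matrix.site_ids)]
    if missing:
        raise ValueError(f"sites absent from matrix: {missing}")
    if not model.site_ids:
        return np.zeros(matrix.n_samples)
    sub = matrix.to_m().subset_sites(model.site_ids)
    mean = model.standardization["mean"].to_numpy()[:, None]
    sd = model.standardization["sd"].to_numpy()[:, None]
    z = (sub.values - mean) / sd
    return model.coefficients @ z


def stratified_kfold(event_labels, gender_labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic fold assignment stratified on gender x event status.

    Within each stratum cell, samples are shuffled (seeded) and dealt
    round-robin, so per-cell fold counts differ by at most one. If any cell
    is smaller than k, stratification falls back to event status only
    (with a logged warning).
    """
    events = np.asarray(event_labels)
    genders = np.asarray(gender_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(events)
    rng = np.random.default_rng(seed)
    cells = pd.Series([f"{g}|{e}" for g, e in zip(genders, events)])
    if cells.value_counts().min() < k:
        logger.warning("a gender x event cell is smaller than k=%d; "
                       "falling back to event-only stratification", k)
        cells = pd.Series([str(e) for e in events])
    folds = np.empty(n, dtype=int)
    # the round-robin deal continues across cells sharing an event status,
    # so per-fold event totals also differ by at most one
    cursor: dict = {}
    for key, idx in sorted(cells.groupby(cells).groups.items()):
        idx = np.array(list(idx))
        rng.shuffle(idx)
        ev = key.split("|")[-1]
        start = cursor.get(ev, 0)
        folds[idx] = (start + np.arange(len(idx))) % k + 1
        cursor[ev] = (start + len(idx)) % k
    return folds


def _fit_weighted_logistic(X, y, w, ridge: float = 1e-6):
    """Weighted logistic fit; returns a predict(Xnew)->risk callable.

    Uses IRLS via statsmodels GLM with frequency weights; on separation or
    non-convergence falls back to a lightly ridge-penalized IRLS
    (penalty 1e-6) with a logged warning.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(tol=1e-8, maxiter=100)
        beta = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta[1:])) > 1e3:
            raise ValueError("separation suspected")
    except Exception:
        logger.warning("weighted logistic fit unstable; ridge fallback (penalty %g)", ridge)
        beta = _ridge_irls(Xc, np.asarray(y, float), np.asarray(w, float), ridge)

    def predict(Xnew):
        Xn = sm.add_constant(np.asarray(Xnew, float), has_constant="add")
        eta = Xn @ beta
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

    return predict


def _ridge_irls(Xc, y, w, lam, max_iter=100, tol=1e-8):
    """IRLS for L2-penalized weighted logistic regression (intercept unpenalized)."""
    p = Xc.shape[1]
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    dev = np.inf
    for _ in range(max_iter):
        eta = np.clip(Xc @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / v
        W = w * v
        beta = np.linalg.solve(Xc.T @ (W[:, None] * Xc) + pen, Xc.T @ (W * z))
        with np.errstate(divide="ignore"):
            new_dev = -2.0 * np.sum(w * (y * np.log(np.clip(mu, 1e-12, None))
                                         + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
        if abs(new_dev - dev) < tol:
            break
        dev = new_dev
    return beta


def cv_predict(features, outcome, weights, folds, model_label: str = "model",
               sample_ids=None) -> RiskPrediction:
    """Pooled held-out risks from per-fold weighted logistic models.

    For each fold, a model is trained on the remaining folds (subjects with
    zero weight are excluded from training) and predicts the held-out
    subjects, so every sample receives exactly one prediction.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=int)
    w = np.asarray(weights, dtype=float)
    folds = np.asarray(folds, dtype=int)
    n = len(y)
    if sample_ids is None:
        sample_ids = list(range(n))
    risks = np.full(n, np.nan)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test & (w > 0)
        predict = _fit_weighted_logistic(X[train], y[train], w[train])
        risks[test] = predict(X[test])
    table = pd.DataFrame({"sample_id": list(sample_ids), "fold_id": folds,
                          "predicted_risk": risks})
    return RiskPrediction(table=table, model_label=model_label)


def mrs_cv_pipeline(matrix: MethylationMatrix, phenotypes: PhenotypeTable,
                    w_samp, horizon: float, k: int = 5, seed: int = 0,
                    mode: str = "full", delta_beta_threshold: float = 0.02,
                    q_threshold: float = 0.05,
                    model: CovariateModelSpec | None = None) -> dict:
    """End-to-end cross-validated prediction for the three risk models.

    Runs the primary-model EWAS, selects sites (q < q_threshold and
    |delta_beta| >= delta_beta_threshold), builds the MRS, recomputes
    censoring weights per training fold, and returns pooled cross-validated
    RiskPredictions for "MRS", "clinical" and "MRS+clinical", plus the
    fitted MrsModel and selected sites.

    mode="full": selection/coefficients from the full data, CV over the
    logistic stage only. mode="nested": selection/coefficients refit within
    each training fold.
    """
    if mode not in ("full", "nested"):
        raise ValueError("mode must be 'full' or 'nested'")
    model = model or CovariateModelSpec.model_1()
    times, events = phenotypes.time_years, phenotypes.event
    w_samp = np.asarray(w_samp, dtype=float)
    genders = phenotypes.table["gender"].to_numpy()
    folds = stratified_kfold(events, genders, k=k, seed=seed)
    w_cens = censoring_weights(times, events, horizon=horizon)
    w_final = w_samp * w_cens
    clin = phenotypes.covariate_matrix(CLINICAL_COVARIATES)

    full_scan = ewas_scan(matrix, phenotypes, model, weights=w_samp)
    selected = delta_beta_filter(
        [r for r in full_scan if r.q < q_threshold and r.converged],
        threshold=delta_beta_threshold)
    mrs_model = build_mrs(selected, matrix) if selected else \
        MrsModel([], np.empty(0), pd.DataFrame(columns=["mean", "sd"]))

    n = phenotypes.n_samples
    mrs_vals = np.zeros(n)
    if mode == "full":
        if selected:
            mrs_vals = score_mrs(mrs_model, matrix)
    else:
        for fold in np.unique(folds):
            test = folds == fold
            train_ids = [sid for sid, t in zip(phenotypes.sample_ids, test) if not t]
            sub_pheno = phenotypes.subset(train_ids)
            sub_matrix = matrix.subset_samples(train_ids)
            scan = ewas_scan(sub_matrix, sub_pheno, model, weights=w_samp[~test])
            sel = delta_beta_filter(
                [r for r in scan if r.q < q_threshold and r.converged],
                threshold=delta_beta_threshold)
            if sel:
                fold_model = build_mrs(sel, sub_matrix)
                mrs_vals[test] = score_mrs(fold_model, matrix.subset_samples(
                    [sid for sid, t in zip(phenotypes.sample_ids, test) if t]))

    feature_sets = {
        "MRS": mrs_vals[:, None],
        "clinical": clin,
        "MRS+clinical": np.column_stack([mrs_vals, clin]),
    }
    predictions = {}
    for label, X in feature_sets.items():
        risks = np.full(n, np.nan)
        for fold in np.unique(folds):
            test = folds == fold
            # censoring weights recomputed on the training folds only
            w_cens_tr = censoring_weights(times[~test], events[~test], horizon=horizon)
            w_tr = w_samp[~test] * w_cens_tr
            usable = w_tr > 0
            predict = _fit_weighted_logistic(X[~test][usable], events[~test][usable],
                                             w_tr[usable])
            risks[test] = predict(X[test])
        predictions[label] = RiskPrediction(
            table=pd.DataFrame({"sample_id": phenotypes.sample_ids,
                                "fold_id": folds, "predicted_risk": risks}),
            model_label=label)
    return {"predictions": predictions, "mrs_model": mrs_model,
            "selected": selected, "folds": folds, "w_final": w_final,
            "scan": full_scan}
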