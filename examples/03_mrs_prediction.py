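"""Cross-validated risk prediction with a methylation risk score.

Runs the full default pipeline: primary-model EWAS, site selection, MRS
construction, and stratified 5-fold weighted-logistic prediction for three
models (MRS alone, clinical risk factors alone, and their combination),
then compares the pooled cross-validated ROC curves.
"""

import numpy as np

from methrisk import (SimulationConfig, compare_auc, mrs_cv_pipeline,
                      roc_curve, simulate_cohort)

cfg = SimulationConfig(n_subjects=752, n_sites=300, n_causal_sites=10,
                       causal_log_hr_per_sd=0.7, seed=42)
phenotypes, matrix, _ = simulate_cohort(cfg)

run = mrs_cv_pipeline(matrix, phenotypes, np.ones(phenotypes.n_samples),
                      horizon=cfg.admin_censor_years, seed=42)

print(f"sites in the MRS: {len(run['mrs_model'].site_ids)}")
aucs = {}
for label, pred in run["predictions"].items():
    aucs[label] = roc_curve(pred.predicted_risk, phenotypes.event).auc
    print(f"cross-validated AUC, {label}: {aucs[label]:.3f}")

p = compare_auc(run["predictions"]["MRS+clinical"].predicted_risk,
                run["predictions"]["clinical"].predicted_risk,
                phenotypes.event)
print(f"DeLong p, MRS+clinical vs clinical: {p:.2e}")

# The methylation signal lifts discrimination well above the
# clinical-factor baseline; the DeLong test confirms the paired AUC gap on
# the pooled held-out predictions.
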