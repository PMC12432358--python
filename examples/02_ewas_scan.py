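"""Run a weighted-Cox EWAS and select robust, large-effect sites.

Scans every CpG site with the primary covariate model (age, gender, BMI,
HbA1c), applies BH-FDR, requires robustness in a second model that adds
medication flags and the smoking proxy, and finally keeps sites whose
event-vs-control beta difference is at least 2%.
"""

import numpy as np

from methrisk import (CovariateModelSpec, SimulationConfig, delta_beta_filter,
                      ewas_scan, robustness_screen, simulate_cohort)

cfg = SimulationConfig(n_subjects=752, n_sites=300, n_causal_sites=10,
                       causal_log_hr_per_sd=0.7, seed=42)
phenotypes, matrix, truth = simulate_cohort(cfg)

model1 = CovariateModelSpec.model_1()
model3 = CovariateModelSpec(3, model1.covariate_names +
                            ["med_lipid", "med_antihypertensive", "smoking_proxy"])

scan1 = ewas_scan(matrix, phenotypes, model1)
scan3 = ewas_scan(matrix, phenotypes, model3)

primary_hits = [r for r in scan1 if r.q < 0.05]
robust = robustness_screen(scan1, {3: scan3})
selected = delta_beta_filter(robust, threshold=0.02)

print(f"sites scanned: {len(scan1)}")
print(f"q < 0.05 in the primary model: {len(primary_hits)}")
print(f"also p < 0.05 in the adjusted model: {len(robust)}")
print(f"and |delta-beta| >= 2%: {len(selected)}")
truth_hits = set(r.site_id for r in selected) & set(truth.causal_site_ids)
print(f"of which truly causal: {len(truth_hits)}")
for r in selected[:5]:
    print(f"  {r.site_id}: HR/SD={r.hr_per_sd:.2f}, q={r.q:.2e}, "
          f"delta-beta={100 * r.delta_beta:+.1f}%")

# HRs per 1 SD of methylation around 0.5 or 2.0 reflect the planted
# |log-HR| = 0.7; the delta-beta column shows the selection is restricted
# to sites whose group difference would be visible on the array.
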