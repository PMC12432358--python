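"""Generate a synthetic prospective T2D cohort and inspect its structure.

Builds a cohort of 752 newly diagnosed subjects with 300 CpG sites, 10 of
which carry a planted log-hazard effect of |0.7| per SD of methylation,
then prints the realized event rate, follow-up distribution and
methylation spread.
"""

import numpy as np

from methrisk import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_subjects=752, n_sites=300, n_causal_sites=10,
                       causal_log_hr_per_sd=0.7, seed=42)
phenotypes, matrix, truth = simulate_cohort(cfg)

events = phenotypes.event
print(f"subjects: {phenotypes.n_samples}, events: {events.sum()} "
      f"({100 * events.mean():.1f}%)")
print(f"follow-up years: mean {phenotypes.time_years.mean():.2f}, "
      f"max {phenotypes.time_years.max():.2f}")
print(f"mean per-site beta SD: {matrix.values.std(axis=1, ddof=1).mean():.4f}")
print(f"causal sites: {truth.causal_site_ids[:3]} ... "
      f"({len(truth.causal_site_ids)} total, effects +-{cfg.causal_log_hr_per_sd})")

# The event rate sits near the 13.6% target because the baseline hazard is
# calibrated by bisection; beta SD sits near 0.05 by the delta-method choice
# of the M-scale spread.
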