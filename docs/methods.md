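# Methods

This note documents the statistical models implemented in `methrisk`, the
design choices made where the problem was genuinely open, the synthetic
data generator's assumptions, and the package's known limitations.

## Data model

Methylation is stored as beta-values (methylated fraction, in [0, 1]) and
converted on demand to M-values, M = log₂(β/(1−β)), which are closer to
Gaussian and are what every model fits; group means and the event–control
difference ("delta-beta") are reported on the beta scale, which is how
methylation differences are read clinically. Exact 0/1 beta-values are
clipped to [1e−6, 1−1e−6] before the logit. The raw-intensity form
M = log₂((max(M,0)+1)/(max(U,0)+1)) is provided for completeness; the
pipeline otherwise treats supplied beta-values as already normalized.
Missing values are not permitted after loading (complete-case analysis);
matrix I/O uses one rigid CSV dialect (comma, decimal point, mandatory
header) and round-trips values exactly. Probe masks (detection-p failures,
cross-reactive, polymorphic probes, ...) are applied as a set union with
per-mask removal counts logged.

## Inverse-probability weights

Sampling weights W_samp undo outcome-dependent sampling from a source
cohort: cohort count / sampled count, per outcome stratum (cases,
controls). When the analyzed sample *is* the cohort, all weights are 1.

Censoring weights W_cens implement IPCW for the fixed-horizon binary
endpoint "event by end of study" used by the logistic stage. Let G(t) be
the Kaplan–Meier probability of remaining uncensored (censoring treated as
the event of interest; reaching the administrative horizon is complete
follow-up, not censoring). Subjects observed to an event at T get
1/G(T−); subjects event-free at the horizon get 1/G(horizon−); subjects
censored event-free earlier get weight 0 — their mass is redistributed to
those still at risk, which is what makes the weighted event frequency
estimate the true cumulative incidence. Three details the weighting scheme
does not pin down by itself, fixed here and exposed as options:

- G is evaluated at the left limit of the subject's own time (the subject
  does not count its own censoring risk).
- G is clipped below at 0.05 (weights capped at 20) for variance control;
  configurable, with a logged count of clipped subjects.
- Early-censored subjects are excluded (weight 0) by default; the
  alternative reading, under which every subject keeps a positive weight,
  is available as `keep_early_censored=True`.

The Cox stage consumes W_samp only — censoring is handled by the partial
likelihood itself; the logistic stage consumes W_samp × W_cens.

KM estimation follows the standard product-limit form with weighted event
and at-risk counts; at tied times events precede censorings.

## Weighted Cox fitting

The per-site fitter maximizes the weighted Breslow partial likelihood by
Newton–Raphson with step-halving, converging when the largest score
component falls below 1e−8 (cap 50 iterations). Breslow tie handling was
chosen because it remains exact under case weights: integer weight w is
identical to duplicating the subject w times, a property the test suite
checks to 1e−8 and which would not hold for Efron's correction.
Non-convergence or a coefficient escaping |β| > 20 (monotone likelihood /
separation) is flagged on the result, not raised, so a genome-wide scan
carries failed sites as flagged rows instead of dying. Standard errors
come from the inverse observed information; p-values are two-sided Wald.

Each site enters its own model as the M-value standardized to unit SD
(unweighted SD on the analysis sample), so hazard ratios read "per 1 SD of
methylation". Whether a weighted SD would be preferable is undecidable
without a stated convention; the unweighted choice is flagged here.

## Multiple testing, robustness and selection

q-values are Benjamini–Hochberg step-up (the common EWAS default among FDR
estimators): q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1. Site selection is:
q < 0.05 in the primary model AND p < 0.05 in every supplied secondary
model (recorded per site) AND |delta-beta| ≥ 2% (inclusive boundary). The
2% threshold is an arbitrary robustness filter on the effect's absolute
size, not an inferential quantity.

## MRS and cross-validated prediction

The MRS is Σ coef_s · z_s with coefficients equal to the primary-model log
hazard ratios and z the site's standardized M-value, so it is invariant to
per-site location shifts. Predicted risks come from weighted logistic
regression (IRLS via statsmodels GLM; |Δdeviance| < 1e−8, ≤100
iterations), with a lightly ridge-penalized IRLS fallback (λ = 1e−6,
intercept unpenalized) on separation. Folds are dealt round-robin within
gender × event cells after a seeded shuffle, with the deal continuing
across cells of the same event status so per-fold event totals differ by
at most one; if a cell is smaller than k the stratification falls back to
event status only. Censoring weights are recomputed on each training fold
(the alternative — freezing full-data weights — differs negligibly but
would let the held-out fold influence training weights).

Two modes govern where the MRS comes from:

- **full mode** (default): site selection and coefficients from the
  full-data EWAS; cross-validation covers the logistic stage only. This
  mirrors the design in which a published score is then evaluated by CV,
  and it leaks selection information into the held-out folds.
- **nested mode**: the EWAS, selection and standardization are refit
  inside each training fold. This is the honest generalization estimate;
  on synthetic cohorts its AUC is on average below full mode's, which
  quantifies the selection leakage the default design implies.

## Evaluation

ROC curves are empirical step functions over all distinct thresholds
(inclusive ≥ semantics); AUC is the trapezoid area and equals the
Mann–Whitney probability with ties counted half, also under weights.
Paired AUCs are compared with DeLong's test (a design choice; no test is
canonical for pooled CV predictions, and DeLong is the standard for paired
ROC on one sample). The Youden cutoff maximizes J = sens + spec − 1 over
observed thresholds, ties broken toward the lower cutoff; J ≤ 0 logs a
warning. Screening reports derive confusion counts by rounding
sens·n_events and spec·n_controls half-away-from-zero, and PPV/NPV/
accuracy by Bayes' rule at the prevalence quoted at screening-report
precision (one decimal of a percent) — the convention under which such
summary diagrams are printed, and the one that reproduces their numbers
exactly.

NRI uses two categories split at the supplied cutoff (categorical) or any
risk change (continuous); components are (P(up|event) − P(down|event)) and
(P(down|non-event) − P(up|non-event)), reported separately and summed. IDI
is the difference of mean risk changes between events and non-events.
Both use the standard asymptotic variance estimators with Wald CIs.

Survival stratification dichotomizes at the cutoff with strict ">" (the
boundary is the last acceptable "negative" value and goes low), then
reports per-stratum KM curves, the unweighted two-group log-rank test
(weights enter only the Cox HR, matching the analysis being emulated), and
a single-covariate weighted Cox HR with Wald CI. A stratum without events
yields a flagged one-sided bound instead of an exception.

## Synthetic cohort generator

The generator defines the study conditions the tests run under:

- **Cohort**: default 752 subjects, target event fraction 13.6% within an
  administrative horizon of 7.2 years, plus exponential random censoring
  (rate 0.15/yr), giving mean follow-up near 4 years. Event times follow
  an exponential-baseline proportional-hazards model — the simplest law
  satisfying the weighted-Cox assumptions. When no baseline hazard is
  supplied it is calibrated by bisection on its logarithm (40 iterations)
  against the realized inverse-transform draws, which is monotone and
  deterministic, so the observed event fraction lands on the target up to
  binomial noise.
- **Methylation**: per-site beta means uniform on (0.1, 0.9); M-values
  Gaussian per site with the M-scale SD set by the delta method
  (dβ/dM = ln2·β(1−β)) so the realized beta-scale SD ≈ 0.05. Causal sites
  contribute log-HR per SD of M-value, with hyper- and hypomethylated
  directions planted in equal proportion (no direction convention is
  imposed).
- **Covariates**: age ~ N(60.6, 11.4), BMI ~ N(31.5, 5.4), HbA1c ~
  N(63.5, 17.9) mmol/mol, cg05575921 beta ~ N(0.78, 0.085), 56% male,
  medication prevalences 15/21/42% — the ranges of a newly diagnosed T2D
  cohort. Default log-hazard effects: age +0.035/yr, male +0.30, HbA1c
  −0.012 per mmol/mol, smoking proxy −4.0 per beta unit (lower AHRR
  methylation, i.e. smoking, raises risk). These magnitudes give the
  clinical-only model a modest AUC, leaving headroom for the methylation
  signal, as in the cohort being emulated.
- All draws come from one `numpy` Generator seeded by the config, so equal
  seeds give byte-identical cohorts.

What the generator does **not** emulate: array intensities and probe-type
effects, batch effects, cell-composition mixtures, correlation between
neighbouring CpGs, two-cohort (discovery source) structure, and
covariate–methylation dependence beyond the hazard. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the assumed generating law — not that real arrays meet those
assumptions.

The a-priori power function is the two-sided normal-approximation power
for a difference of means, Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2}) with
λ = |Δ|/(σ√(1/n₁+1/n₂)); the symmetric form returns exactly α at Δ = 0.

## Test-suite problem sizes and statistical checks

Simulation-backed tests run at sizes chosen to keep the default suite
fast while leaving the checks well-powered: null EWAS calibration at
1000 sites × 800 subjects (type-I error within 3 binomial SDs of α);
parameter recovery at n = 2000 via a weighted-Cox refit of the generating
model — the per-site marginal scan is attenuated by non-collapsibility
when other causal sites are omitted, so "within 3 SE" is asserted on the
joint refit while the marginal scan is required to discover every planted
site; BH false-discovery behaviour over 60 null scans — because BH's weak
family-wise error sits exactly at α under the global null, the "zero
discoveries in ≥95% of runs" property is checked as a one-sided binomial
consistency bound at the 0.01 level rather than as a point threshold; and
pipeline discrimination over 20 seeds at 600 subjects × 300 sites.

## Known limitations

- Breslow ties only (Efron not implemented); fine for continuous or
  lightly tied times.
- Wald inference throughout; no profile-likelihood or bootstrap CIs.
- The logistic stage treats "event by end of follow-up" as a binary
  outcome; subjects are exchangeable only through the IPC weights, and the
  weight-0 default discards early-censored subjects' covariate
  information.
- DeLong's variance treats pooled CV predictions as one paired sample,
  ignoring between-fold dependence.
- NRI/IDI variances are the standard asymptotic forms, which are known to
  be anti-conservative for nested models under the null.
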