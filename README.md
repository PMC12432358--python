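# methrisk

Blood DNA-methylation biomarkers for predicting incident macrovascular
events (myocardial infarction, angina, ischemic heart disease, stroke) in
newly diagnosed type 2 diabetes.

Clinical risk calculators discriminate poorly in newly diagnosed T2D, where
most patients have few classical risk factors yet carry very different
cardiovascular risk. `methrisk` implements, as a tested reusable pipeline,
an epigenome-wide survival analysis of blood methylation and the
construction and evaluation of a methylation risk score (MRS) as a
screening test — together with a synthetic cohort generator that emulates
the statistical structure of such a prospective cohort (~750 subjects,
~13.6% events within a 7.2-year administrative horizon, per-site
beta-value SD ≈ 0.05), so every stage is testable without access-restricted
patient data.

## The model

For CpG site $s$ with standardized M-value $z_s$ (M = logit₂ of the
methylation fraction β), the per-site association with time to first
macrovascular event is a weighted Cox proportional-hazards model

$$\lambda_i(t) = \lambda_0(t)\,\exp\!\big(\beta_s z_{s,i} + \gamma^\top x_i\big),$$

fitted by Newton–Raphson on the Breslow partial likelihood with
inverse-probability-of-sampling weights $W_{samp}$ (cohort count /
sampled count per outcome stratum). $\exp(\beta_s)$ is the hazard ratio
per 1 SD of methylation; $x$ holds the covariate adjustment set (model 1:
age, gender, BMI, HbA1c; richer models add cell composition, medications,
the smoking proxy cg05575921 and lipids). Sites with BH-FDR $q<0.05$ in
model 1, $p<0.05$ in every secondary model, and an absolute event–control
beta difference ≥ 2% enter the score

$$\mathrm{MRS}_i = \sum_{s \in \text{selected}} \hat\beta_s\, z_{s,i}.$$

Predicted event risks come from weighted logistic regression
(weights $W_{samp} \times W_{cens}$, where $W_{cens}$ is an inverse
probability of censoring weight from a Kaplan–Meier estimate of remaining
uncensored) under 5-fold cross-validation stratified on gender and event
status. Discrimination is evaluated by ROC/AUC (with DeLong comparison),
precision–recall, the Youden cutoff with prevalence-based PPV/NPV, NRI and
IDI against the clinical-only model, and Kaplan–Meier / log-rank /
weighted-Cox stratification of the dichotomized score.

## Worked example

```sh
python examples/03_mrs_prediction.py
```

```
sites in the MRS: 8
cross-validated AUC, MRS: 0.898
cross-validated AUC, clinical: 0.574
cross-validated AUC, MRS+clinical: 0.900
DeLong p, MRS+clinical vs clinical: 3.36e-24
```

On a synthetic cohort of 752 subjects with 10 causal CpG sites planted at
|log-HR| = 0.7 per SD, the pipeline selects 8 sites (all truly causal),
and the pooled held-out AUC of the MRS-based models far exceeds the
clinical-factor baseline — the synthetic analogue of a methylation score
adding predictive value over clinical risk factors. The other example
scripts walk through cohort generation (`01`), the EWAS with robustness
and effect-size selection (`02`), screening-test evaluation at the Youden
cutoff with NRI/IDI (`04`), and survival stratification (`05`).

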