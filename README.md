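# multistress

Predicting the combined effects of chemical and environmental stressors on
aquatic invertebrates, and quantifying how far observation departs from the
predictions — the analysis chain of a multi-stressor acute-toxicity study
on *Gammarus pulex* exposed to the neonicotinoid clothianidin, the azole
fungicide prochloraz and elevated temperature, with pesticide-adapted
(agricultural-stream) and non-adapted (reference-stream) populations.

It is written for ecotoxicologists and risk assessors who have
treatment-level immobility counts (or want to simulate them) and need:

* **Dose–response fitting.** The five-parameter log-logistic (LL5) model
  for the immobile fraction at dose *t*,

  *E*(*t*) = *c* + (*d* − *c*) / (1 + exp{*b* [ln *e* − ln *t*]})^*f*,

  fitted by binomial maximum likelihood (a dozen animals per treatment is
  far from Gaussian), with ECx extraction and profile-likelihood or
  delta-method confidence intervals.
* **Null models.** Concentration addition (Loewe; ECx_mix =
  (Σ *p*ᵢ/ECxᵢ)⁻¹) and effect addition / independent action (Bliss;
  *E*_mix = 1 − Π(1 − *E*ᵢ)).
* **The stress addition model (SAM).** Every stressor's effect is converted
  into a dimensionless *General-Stress* level against a shared beta
  stress-capacity distribution on [0, 1]: survival *N*(*S*) = 1 − *F*(*S*),
  with *N*(0) = 1 and *N*(*S* ≥ 1) = 0. Independently acting stressors add
  on the stress scale, *S* = Σ *S*ᵢ, and the sum is transformed back to
  survival.
* **Synergy quantification.** The model deviation ratio
  MDR = EC50_predicted / EC50_observed, classified as antagonism (< 0.5),
  additivity (0.5–1), weak (1–2) or strong (> 2) synergism; group
  comparisons (pooled/Welch/paired *t*) and the regression of EA-based MDR
  on total General-Stress.
* **Toxic units** for field exposure, TU = log₁₀(*C*ᵢ / EC50ᵢ), with
  per-sample TU_max and site-level aggregation.
* **A synthetic experiment generator** reproducing the study's full
  factorial (9 clothianidin doses × 3 prochloraz levels × 3 temperatures ×
  4 reference + 8 agricultural stream populations, 12 animals per stream
  and treatment) with known ground truth, so every stage is testable
  without the unpublished raw data.

## Worked example

```python
import multistress as ms

table, truth = ms.generate_experiment(ms.SyntheticConfig(seed=1))
study = ms.MultiStressStudy(table)

# population-level tolerance at the reference temperature
ref = study.curve(("reference", 16.0, 0.0)).ec(50, ci="profile")
agr = study.curve(("agricultural", 16.0, 0.0)).ec(50, ci="profile")
print(f"ref EC50 {ref.dose:.1f} [{ref.ci_low:.1f}, {ref.ci_high:.1f}]")
print(f"agr EC50 {agr.dose:.1f} [{agr.ci_low:.1f}, {agr.ci_high:.1f}]")
print("fold tolerance:", ms.fold_tolerance(agr.dose, ref.dose))

# combined-effect prediction under the multiple-stress design
results = study.fit(ms.multiple_stress_design(), models=("EA", "SAM"))
print(results.summary())

# synergism vs total General-Stress (EA null model, both designs)
reg = ms.synergism_regression(ms.synergy_points(study))
print(f"slope={reg.slope:.2f} r2_adj={reg.r2_adj:.2f} df_resid={reg.df_resid}")
```

prints (abridged):

```
ref EC50 63.9 [40.9, 90.4]
agr EC50 152.3 [125.2, 184.1]
fold tolerance: 2.4
Combined-effect predictions (multiple_stress)
  population  temperature  prochloraz model  observed_ec50  predicted_ec50  mdr   classification
agricultural         19.0         0.0    EA          59.18          152.28 2.57 strong_synergism
agricultural         19.0         0.0   SAM          59.18           69.83 1.18   weak_synergism
...
slope=5.47 r2_adj=0.20 df_resid=22
```

The agricultural population is ~2.4-fold more tolerant to clothianidin
than the reference population in this simulated run (true values 148 vs
67 µg/L). Under warming the effect-addition null model predicts EC50s far
above what is observed (MDR up to ~2.6 here: strong synergism), while the
SAM — which converts the extra stressors into General-Stress and adds them
— stays much closer to the observation (MDR near 1). The regression slope
is positive: synergism strengthens as total General-Stress grows.

The same pipeline runs from the shell:

```
multistress simulate --seed 1 --out table.csv
multistress predict --model sam --input table.csv --design multistress
multistress synergy-report --design mixture --input table.csv
multistress tu --input chem.csv
```

Published joint-effect estimates for the motivating study are bundled for
comparison: `ms.load_joint_effects()`.

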