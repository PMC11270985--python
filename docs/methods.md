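# Methods

## Dose–response model

Immobility after 48 h is modelled per treatment as a binomial count whose
probability follows the five-parameter log-logistic curve

E(t) = c + (d − c) / (1 + exp{b [ln e − ln t]})^f

with slope b > 0 (immobility nondecreasing in dose), background immobility
c (the lower asymptote, reached as t → 0), maximal effect d, inflection
dose e (µg/L) and asymmetry f. With f = 1 the curve is symmetric on the
log-dose axis and e equals the EC50. The control (dose 0) sits on the
lower asymptote and is never log-transformed. Survival (mobility) is
1 − E throughout; there is no separate control correction — c absorbs
background immobility.

Estimation maximises the binomial likelihood: with treatments of a dozen
animals the Gaussian assumption behind least squares on proportions is
poor. A least-squares mode (`fit(method="ls")`) is kept for cross-checks
against conventional dose–response software. Internally the model is
reparameterised as (log b, logit c, logit r, log EC50, log f) with
d = c + (1 − c)r, so that the log EC50 is itself a free parameter;
starting values come from a logit-linear regression on interpolated
proportions, refined over a fixed deterministic jitter ladder (no RNG in
fitting — refits are bit-identical). Replicate rows sharing a dose are
pooled, making fits invariant to row order and to how a treatment's count
is split across rows.

The optimizer box constrains b to [0.1, 10] and f to [0.2, 5]. This is a
biological-plausibility constraint with a numerical purpose: on a coarse
dose grid (consecutive doses an order of magnitude apart) an unbounded
slope lets the likelihood collapse onto a step function whose EC50 snaps
to the edge of a dose gap, which produces absurd downstream MDRs. Slopes
of acute immobility curves in amphipods sit well inside this box.

**ECx.** The default ECx is *relative* (rescaled between the asymptotes
c and d); an *absolute* scale is available by flag, since published
analyses rarely state which convention their software used. Confidence
intervals are profile likelihood by default (the deviance is profiled
over log ECx with the other four parameters re-optimised; 95% cutoff
χ²₁ = 3.84), with a delta-method alternative on the log-dose scale from
the pseudo-inverse of the observed-information matrix.

Coverage of the profile interval is near-nominal (≈ 0.95 in simulation)
when the true EC50 lies near a tested dose, and degrades when it falls
mid-gap: nine binomial observations nearly saturate a five-parameter
model, so the profile can be too tight where the grid carries no
information. This is a property of the design, not of the estimator;
denser grids restore nominal coverage.

Data in which every dose responds all-or-nothing are rejected with a fit
error rather than silently interpolated — the slope is unidentifiable and
any EC50 between the two step doses fits equally well.

## Null models for combined effects

*Effect addition* (EA, independent action): E_mix = 1 − Π(1 − E_i).
*Concentration addition* (CA): ECx_mix = (Σ p_i / ECx_i)⁻¹ for relative
concentration fractions p_i summing to 1 (the sham-combination identity —
a mixture of a compound with itself changes nothing — holds exactly).

For a primary toxicant under a co-stressor with fixed marginal effect
E_cos, the predicted EC50 is defined *relative to the combined control*
(the co-stressor-only treatment), matching how observed EC50s are
compared with their own co-stressed controls:

* **EA** solves 1 − (1 − E(t))(1 − E_cos) = midpoint of the combined
  range by bisection on log dose. For a binary mixture this rescaling
  makes the prediction coincide with the unstressed EC50 — the
  co-stressor lifts the control and the response jointly — which is why
  EA-predicted EC50s track the control EC50.
* **CA** converts E_cos into an equivalent dose of the primary toxicant
  through the inverse of its fitted curve (equivalently, under parallel
  curves, the co-stressor's toxic-unit fraction) and subtracts it on the
  Loewe isobole: EC50_pred = EC50 − dose_equivalent. A co-stressor at or
  above 50% effect leaves no finite CA prediction (domain error). In the
  study pipeline only the *chemical* co-stressor contributes a dose
  equivalent — concentration addition sums concentrations, and
  temperature has none — so for temperature-only comparisons CA predicts
  the control EC50.

The co-stressor's marginal effect is estimated as the condition curve's
fitted lower asymptote, Abbott-corrected against the control curve's
asymptote. The fitted floor pools the control and low-dose arm of the
design; the raw dose-0 fraction of a single 12-animal treatment would
carry too much binomial noise.

**MDR.** The model deviation ratio is predicted/observed EC50, kept
unrounded internally; reports round half-even at 2 decimals. The
classification partitions (0, ∞): antagonism < 0.5, additive [0.5, 1],
weak synergism (1, 2], strong synergism > 2.

## Stress addition model

The stress-capacity distribution is Beta(α, β) on [0, 1], default
α = β = 3.2 following the established SAM reference implementation — the
framework itself fixes only the boundary behaviour N(0) = 1, N(S ≥ 1) = 0
— and both shapes are configurable. Survival and General-Stress are exact
inverses through the beta CDF/quantile pair.

**Quantifying an added stressor.** The added General-Stress is the mean,
over tested doses in a window around the EC50 of the toxicant alone (the
2 nearest resolvable doses on each side by default; a config knob), of
S(combined survival) − S(alone survival from the fitted curve). Doses
where either response is saturated (survival exactly 0 or 1) are censored
at the capacity bounds and never enter the window; count data use an
Anscombe-type (k + ½)/(n + 1) correction so all-dead or all-alive
treatments remain resolvable. Negative aggregates (combined survival
above the alone fit) are floored at zero with a warning. Per-dose
contributions, censoring and window membership are returned for audit.

**Prediction.** N_pred(t) = N(S(N_tox(t)) + S_env). The SAM EC50 is the
dose where N_pred crosses the midpoint of its own range between the
stressed control and the high-dose plateau (effect relative to the
stressed control, default); scaling to the unstressed control is
available by flag since published usage does not state the choice. With
S_env = 0 both reduce to the unmodified EC50.

Self-consistency follows by construction: quantifying a co-stressor's
General-Stress from a condition's own (forward-generated) data and
predicting with it returns the observed EC50 exactly, MDR = 1. This is
the property the acceptance script recomputes.

## Comparison designs and the synergism regression

Two layouts cover the study's questions. *Mixture toxicity* compares each
(population, temperature, prochloraz > 0) condition with the
prochloraz-free control at the same temperature. *Multiple stress*
compares every elevated-temperature condition (19/22 °C, any prochloraz)
with the best-case control of the same population at 16 °C without
prochloraz. Observed EC50s are fitted on survival pooled per population
class (averaging across stream populations), and records are ordered
deterministically by (population, temperature, prochloraz).

Synergy points pool both designs (24 points under the default factorial:
12 conditions per design × 2 populations). The x-coordinate sums the
General-Stress of every stressor separating a condition from its control:
prochloraz stress from the reference population's same-temperature shift,
warming stress from the reference 16 °C shift, and — for agricultural
populations — an adaptation-cost term quantified as the excess
General-Stress of the agricultural response over the reference response
under the same co-stressors, floored at zero. How the original analysis
computed that cost is not public; this rule is a documented stand-in
isolated in one function, so the regression against total stress is a
qualitative, not exact, reproduction. The y-coordinate is the EA-based
MDR, and the fit is ordinary least squares with residual df = n − 2.

Group comparisons use a pooled two-sample t when a two-sided F-ratio
pre-check accepts equal variances at α = 0.05, Welch's t otherwise, and a
paired t for matched synergism comparisons; EC50s are ln-transformed by
flag.

## Toxic units

TU = log₁₀(C / EC50_ref) per compound and sample; zero concentrations are
flagged below-detection rather than mapped to −∞ and never enter maxima.
TU_max takes the per-sample maximum (compound-name order breaks ties).
Site aggregation takes the maximum TU_max within each campaign and the
mean of campaign maxima across years — the aggregation statistic is not
standardised, so the rule is recorded in the output. Choosing the most
sensitive reference species is the caller's responsibility; a helper
takes the minimum over candidate reference EC50s.

## Synthetic data generator

The generator emulates the study's full factorial: nine clothianidin
doses (0, 0.01, 0.1, 1, 10, 100, 215, 465, 1000 µg/L) × prochloraz
(0, 1, 10 µg/L) × temperature (16, 19, 22 °C) × two population classes
pooling 4 (reference) and 8 (agricultural) stream populations, each
contributing 12 animals per treatment in three vessels of four. Expected
survival per cell follows the forward SAM: the class's LL5 curve
(reference EC50 67 µg/L, agricultural 148 µg/L at 16 °C; slope 2,
background immobility 0.02, full maximal effect, symmetric), converted to
General-Stress, plus the configured true stresses of prochloraz
(0.04 / 0.10), warming (0.15 / 0.18 at 19 / 22 °C) and, for co-stressed
agricultural animals, an adaptation cost of 0.07. The stress magnitudes
are design fixtures calibrated through the closed-form forward map so
that implied EA-based MDRs span the weak-to-strong synergism range
(~1.2–2.8) reported for comparable conditions; the sidecar labels them as
fixtures, not field estimates. Counts are binomial with one RNG substream
per cell, keyed by a stable hash of (population, stream, temperature,
prochloraz, dose), so extending the design never perturbs existing cells.

What the generator does *not* emulate: stream-to-stream variation in true
tolerance within a class (all streams share the class curve), solvent or
handling mortality beyond the constant background, time-resolved
mortality, and any non-additivity of true stresses. Passing tests
therefore show that the pipeline recovers the forward model's structure
at realistic sample sizes — not that real populations obey it.

## Numerical choices

Root finding uses Brent's method on log dose (xtol 1e-12) with generous
brackets around the curve's inflection; the beta CDF/quantile round trip
is accurate to ~1e-12. Report rounding is half-even. The LL5 likelihood
clips probabilities to [1e-10, 1 − 1e-10]. Profile-CI bracketing expands
in 0.25 log-dose steps and refines by Brent; an unbounded side returns
±∞. Fits at the parameter box report boundary flags rather than failing.

## Known limitations

* On the study's coarse dose grid the LL5 fit of a forward-SAM curve is a
  KL projection, not the curve itself: at large n the fitted relative
  EC50 can sit tens of percent from the underlying curve's midpoint
  crossing when the response jumps across a dose-decade gap. Pipeline
  MDRs therefore converge to the projection-implied values, which the
  end-to-end tests compare against noiseless-proportion fits, not raw
  curve midpoints.
* Profile-CI coverage degrades mid-gap (see above).
* The adaptation-cost stress rule and the cross-year TU aggregation are
  documented stand-ins for unpublished procedures.
* SAM quantification assumes the added stress is dose-independent inside
  the window; strongly dose-dependent interactions violate the model and
  surface as window-heterogeneous audit contributions.
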