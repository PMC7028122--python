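# Methods

This note documents the models behind `tabvis`, the parameters that matter,
how the synthetic cohort is calibrated, and the numerical and design
choices that were genuinely open.

## 1. The face-discrimination staircase

**Task model.** A 4AFC odd-one-out discrimination along a dissimilarity
axis *d*, the Euclidean distance between two faces' 127-point landmark
vectors (`faces.dissimilarity`). Landmark morphing
(`faces.morph`) extrapolates a face away from a reference by a percentage,
so dissimilarity grows linearly with the morph percentage — this is the
axis the staircase walks along.

**Psychometric function.** Weibull on the linear *d* axis:

    p(correct | x, T) = γ + (1 − γ − δ) · (1 − exp(−(x/T)^β))

with γ = 0.25 (4AFC chance), δ = 0.01 (lapse), β = 25 (slope), all
config-exposed (`PsychometricParams`). The slope default deserves
explanation. β ≈ 3.5 is the conventional Weibull slope for staircases
operating on *log* intensity axes; on this linear dissimilarity axis it
would make the 20-trial threshold estimate wander with an SD of ≈ 0.38 d
and acquire a posterior-skew bias of ≈ +0.04 d. Both are incompatible with
what these tests measure in practice: within-visit repeatability of
CoR₉₅ ≈ 0.27 d implies a per-run estimation SD of only
0.27/(1.96·√2) ≈ 0.097 d at ~20 trials. Discriminating natural face images
along a landmark-distance axis is close to step-like at threshold, and
β = 25 — which yields a 20-trial SD of ≈ 0.088 d and |bias| ≤ 0.006 d — is
the slope calibrated to that observed repeatability. Users studying
shallow-slope regimes can set β per config.

**Posterior.** 301 evenly spaced candidate thresholds on d ∈ [0.5, 8.0]
(grain 0.025 d), bracketing the typical 3–4 d range with wide margin;
prior = Gaussian(3.5, 2.0) truncated to the domain — broad enough that
data dominate within a few trials. After each trial the posterior is
multiplied by the Bernoulli likelihood of the observed response and
renormalized; a response whose likelihood underflows to zero everywhere
raises `NormalizationError` rather than silently renormalizing garbage.

**Placement and estimate.** Stimuli are placed at the posterior mean
(clamped to the domain); the outcome measure is also the posterior mean,
recomputed after every trial, so the estimate after trial *N* uses trials
1..N only — this is what makes the first-*N* refinement analysis a pure
post-hoc truncation. Posterior-mode placement and a log-spaced domain
(geometric-mean estimate) are available by config but off by default: the
deployed tests report linear *d*.

## 2. The search grid and RT model

The 9-column × 7-row grid fills the 26 cm × 17.3 cm screen; cell centres
are at uniform spacing (2.89 cm × 2.47 cm), the central cell holds the
Reference and is never a target, and eccentricity is
atan(distance from centre / 50 cm), giving targets from 2.83° to 15.35°.
Schedules are seeded permutations visiting each scheduled location exactly
once (62 for the full protocol).

**Refined 22-location subset.** The published refined protocol uses 22
locations whose membership is not enumerated; `REFINED_22` is this
package's documented, *non-canonical* stand-in: 4 inner-ring, 8 mid-field
and 10 outer cells, symmetric under 180° rotation and spanning all
eccentricity bands. It is ordered so its prefixes form the nested
refinement ladder 4 ⊂ 12 ⊂ 22 (⊂ 62), with the sparsest rung the four
screen corners — sparse subsets must stay spatially distributed, otherwise
their median estimates a different (eccentricity-conditional) quantity
than the full-grid median. Both the subset and the ladder are
config-overridable.

**Observer RT model.** Mean RT at eccentricity ε is
s · (a·ε^b + c) seconds, defaulting to the field-fit coefficients
(a, b, c) = (−13.14, −0.05, 13.56) with a per-participant speed multiplier
s; draws are lognormal around the mean with log-SD σ_loc (median-preserving,
strictly positive). Eccentricities below 0.5° are clamped (targets never
occur there; the power law is singular at 0 for b < 0) and the mean is
floored at 0.05 s where the fitted curve would dip non-physical near the
clamp.

## 3. Synthetic cohort calibration

`generate_cohort` emulates the study conditions under which these tests
were evaluated in young normally-sighted adults: 50 participants with
search data, the first 30 of them with reportable faces data, two runs of
each test within a visit, 50 staircase trials and all 62 locations
recorded (analyses then use the first 20 trials / the 22-location subset).
The population parameters are derived in closed form from the summary
statistics those conditions are known to produce, used as calibration
constraints rather than free dials:

* **Faces.** Per-run measurement SD = CoR₉₅/(1.96√2) = 0.097 d, of which
  the staircase itself contributes 0.088 d (measured by simulation at the
  default slope), leaving a run-to-run stability jitter of 0.042 d.
  Population mean 3.2 d (the one free choice, inside the typical 3–4 band);
  the Gaussian 99% limit of 3.50 d then fixes the pooled SD
  (3.50 − 3.2)/z₀.₉₉ = 0.129 d and, by variance subtraction, a
  between-observer SD of 0.084 d.
* **Search.** The noiseless 22-location median of the default power law is
  m₀ ≈ 1.75 s. A Gamma family with mean m₀ and 0.99 quantile 3.1 s fixes
  the total spread of observed medians; per-location log-SD 0.35 (a typical
  RT coefficient of variation — the choice here) contributes ≈ 0.163 s to
  the within-run median SD, and the run-level jitter is set by variance
  subtraction from CoR₉₅ = 0.84 s. The per-observer speed multipliers are
  Gamma with mean 1 and the shape implied by the residual between-observer
  variance.
* **Couplings and covariates.** Face and search latent abilities share a
  Gaussian copula with ρ = 0.18 (the weak association seen between the two
  tests in normal cohorts); covariate→performance correlations (acuity,
  contrast sensitivity, digit span) default to 0, matching the null
  associations, and are settable for power studies. Usability ratings are
  integers drawn from {8, 9, 10} with means 9.6 (faces) and 9.7 (search).

All randomness flows from one seed through named `SeedSequence` spawns
(population, then one stream per participant), so cohorts are reproducible
byte for byte.

**What the generator does and does not emulate.** It reproduces paired
two-run outcomes, trial-by-trial staircase histories, eccentricity-graded
RTs, and population distributions consistent with the calibration targets.
It does not model learning or fatigue across runs (none was observed in
the data being emulated), attention lapses in search, RT outliers heavier
than lognormal, process-of-elimination strategies, or duration/timing of
sessions. Passing tests therefore demonstrate that the *analysis pipeline*
recovers known generating conditions — not that real observers behave like
the generator.

Two degeneracies of the calibrated regime are worth knowing. First,
because the staircase starts at the prior mean (3.55 d), above almost
every healthy observer's threshold, trial-1 responses are nearly always
correct; run-1 and run-2 estimates after one trial then coincide for many
cohorts and the N = 1 point of the faces refinement curve can be
degenerate at zero (the curve instead peaks at N ≈ 2–3 before falling).
Second, the δ = 0.01 lapse rate occasionally produces a wild 20-trial
estimate (a lapse near trial 20 at steep slope throws the posterior),
giving the CoR bootstrap distribution a heavy upper tail in some cohorts.

## 4. Analysis conventions

* **Bland–Altman.** Differences are run2 − run1 (sign affects only the
  bias); SD uses the n−1 denominator; CoR₉₅ = 1.96·SD(diff). The
  √2-inflated within-subject-SD estimator is noted in `repeatability` but
  not used: with exactly two runs the paired-difference form is canonical.
* **BCa bootstrap.** Resamples *pairs* (participants), never individual
  runs, preserving the pairing; z₀ from the fraction of resample
  statistics below the point estimate with ties at half weight; a from
  leave-one-pair-out jackknife skewness; degenerate resample distributions
  return a point-mass interval with a warning. Default N = 20 000.
* **Normative fits.** Gaussian ML uses the n-denominator SD (pure MLE) —
  documented because the 99% cutoff is sensitive to this; Gamma is full ML
  with location fixed at 0 (scipy's digamma-equation shape solve). Pooling
  runs 1 and 2 is gated by a paired t-test (Wilcoxon optional) that warns
  at p < 0.05. Classification is strict: a score exactly at the cutoff is
  `within_norms`.
* **Power-law fit.** `curve_fit` restarted from a grid of exponents and
  both signs of a (the exponent surface is shallow); adjusted R² with 3
  parameters; non-convergence from every start raises with the optimizer's
  last diagnostic.
* **Spearman.** Midrank ties; t-approximation p for n ≥ 20, seeded
  permutation test below (the approximation is unreliable at small n).

## 5. Problem sizes in tests and the acceptance script

Simulation-based checks use sizes chosen to keep sampling error well below
the tolerances being asserted while remaining quick to run: staircase
recovery uses 1000 sessions of 50 trials; BCa coverage 1000 replications
at n = 30 with 999 resamples; normative calibration n = 10 000;
study-reproduction checks take the median over 5 replicate cohorts (the
acceptance script uses 9). CoR-type statistics on n = 30 pairs carry
~13% relative sampling error per cohort (more in the heavy-tail regime
noted above), which is why replicate medians, not single cohorts, are
compared against the calibration targets.

## 6. Known limitations

* The refined 22-location subset is a principled reconstruction, not the
  published layout; pointwise and refinement results tied to exact cell
  identity will differ from deployments using the original subset.
* The Weibull slope calibration ties the generator to healthy-adult
  repeatability; populations with shallower psychometric functions (e.g.
  low-vision observers) would need β and the noise decomposition re-derived.
* Between-visit (intersession) variability is out of scope; the
  repeatability machinery addresses within-visit retest only.
* The cohort's Gamma/Gaussian population families are assumptions of the
  generator, chosen for consistency with the normative fitting families —
  agreement between fit and generator is therefore a calibration check,
  not evidence about real populations.
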