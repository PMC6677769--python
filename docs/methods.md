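# Methods

This note documents the models implemented in `neuroreadout`, the defaults
chosen where the design was open, and what the synthetic-data generator does
and does not emulate.

## Task and synthetic sessions

The simulated experiment is a two-feature 2AFC discrimination. Two dot
patches sit at a 25% contrast, 0% coherence baseline; on each trial both
patches receive base increments of contrast (+7.5, +15, +30 or +60%,
i.e. absolute bases 32.5–85%) and coherence (+15, +30, +45 or +60%), drawn
independently and uniformly per trial so every condition is equally likely
to follow every other (the balance property the deconvolution design relies
on). One side per feature, chosen independently, additionally carries a
small target increment. Runs alternate the cued feature. In 2/5 of runs
(catch runs) trials are post-cued with probability 1/7 to report the
*un-cued* feature; catch runs use a single base level per feature, which is
what gives the 12-fit threshold battery (4 bases × 2 tasks regular, 1 × 2
cued-in-catch-runs, 1 × 2 catch). Scan-mode schedules emit onset volumes at
TR 0.5 s with a 30 s baseline per run and inter-trial intervals drawn from
an exponential truncated to 2–11 s whose scale is solved numerically so the
truncated mean is 6.0 s (drawn by inverse CDF, which is equivalent to
rejection from the same truncated law).

The cued-feature increment is controlled by one PEST staircase per (task,
base) pair — 8 in a standard session. PEST internals are the classic rules:
a Wald sequential test with deviation bound W = 1 around the target
probability (default 0.82), step halving on reversals, step doubling from
the third successive same-direction step (fourth, when the step before the
last reversal was itself doubled), a minimum step of 1e-3 and a level
ceiling at 1 − base. Staircases initialize at 25% (contrast) and 85%
(coherence); the initial step defaults to half the initial level and is
exposed in the config, as is the periodic reset of the step to one third of
the current level. A staircase pinned at its ceiling for five consecutive
decisions is flagged as diverged (an observer at chance).

Choices are Bernoulli draws from the linking model below. The generator's
default ground-truth observer reads out V1 and MT with flexible weights
(contrast task: β_V1 = 13, β_MT = 1; coherence task: β_V1 = 1, β_MT = 21;
bias 0.1; lapse 0.03). The weights were set once from the response-function
slopes so that analytic thresholds land in the empirically observed range —
a few percent contrast at the lowest base, on the order of 0.1 proportion
coherence — and are not tuned thereafter.

BOLD timeseries are formed by linear summation: each event adds its
condition amplitude times a canonical difference-of-gammas HRF
(peak ≈ 5.5 s, undershoot ≈ 15 s, peak-normalized to 1 — only the
unit-amplitude contract matters downstream; the exact shape is a package
default, fully exposed) plus i.i.d. Gaussian noise. An AR(1) knob exists
and defaults off.

What the generator does *not* emulate: real fMRI noise structure (drifts,
physiological noise, spatial correlation), hemodynamic nonlinearity at
short ITIs, learning or attentional lapse dynamics within sessions, and
voxel-level heterogeneity (the unit of simulation is an area's mean
timeseries). Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to every
property of real data.

## Population response functions

Contrast responses are Naka–Rushton with fixed exponents 1.9 (numerator)
and 1.6 (denominator); coherence responses are α_coh(1 − e^(−s/κ)), the
saturating form in which κ marks 63% of asymptote. (The saturating
exponential is sometimes printed with a positive exponent; that form is
non-saturating, so the negative sign is used throughout.) An additive
α_task absorbs task engagement. Per-area contrast amplitudes default to the
published passive-viewing group values (V1 1.68 … MT 0.22 psc); coherence
sensitivity is published as the least-squares *linear slope* of the
coherence response on [0, 1] (V1 0.07 … MT 0.34 psc/unit), so the package
stores κ = 1.0 (the near-linear regime those areas occupy) and backs out
α_coh from the printed slope — the slope, not (α_coh, κ), is the
identifiable quantity. The contrast semi-saturation σ is not published at
area level; the package default is σ = 0.5 for all areas. The slope is
computed on a 101-point grid; tests check it against the exact continuous
projection onto {1, s}.

## Linking model

The decision variable is the difference of weighted readouts plus a bias,
passed through a standard-normal CDF, mixed with a lapse λ/2 floor.
Numerical policies:

* λ is estimated first from suprathreshold errors and held fixed while
  fitting weights. Under the lapse model the asymptotic error rate is λ/2,
  so the estimator is twice the error rate on cued increments ≥15%
  (contrast) or ≥40% (coherence), clipped to [0, 1].
* Fitting is bounded L-BFGS-B on the Bernoulli log-likelihood with weights
  in [−50, 50], bias in [−10, 10], multi-start (default 6 starts: zeros
  plus seeded uniform draws; cross-validation paths use 2–3 starts). The
  objective tolerance is 1e-8; probabilities are clipped at 1e-12 before
  taking logs.
* History variant: four stay/switch predictors (previous choice side ×
  previous correctness), computed within run; the first trial of a run has
  zero history. Efficient-selection variant: per-area responses are raised
  to ρ ≥ 1 before weighting and the aggregate takes the 1/ρ root, both as
  signed powers so negative responses and biases remain defined; ρ is a
  free parameter in [1, 8].
* Poisson-noise variant: the probit scale is set per trial from the
  unweighted mean area response per patch, σ² = (σ²_left + σ²_right)/2
  (a `poisson_combine="sum"` switch implements the alternative reading);
  the variance is floored at 1e-12 against non-positive responses.
* Fixed-mode weights are a strict subspace of flexible-mode weights, so the
  in-sample fixed likelihood can never exceed the flexible one; this
  nesting is asserted in tests.

Implied noise is reported as 1/β per area and task (infinite at β = 0, sign
carried through). Analytic JNDs root-find the increment that raises the
weighted readout by 1 (d′ = 1 at unit probit noise) with `brentq` to 1e-8,
returning non-measurable (NaN) when no increment within 1 − base reaches
the target. Catch-trial predictions evaluate the same root-finding with the
other task's weights (wrong-readout mode) and/or a required difference
equal to a working-memory cost factor. Two threshold conventions coexist
deliberately: analytic model JNDs use the unit-readout-difference rule
(which simulates to Φ(1) ≈ 84% correct), while Weibull/behavioural JNDs and
`simulated_jnd` use the 2AFC d′ = 1 percent-correct criterion
Φ(1/√2) ≈ 76%; `simulated_jnd` is the right notion for the Poisson and
selection variants, where the probit scale is not 1.

## Psychometrics

Cumulative-normal fits use trial-level Bernoulli likelihood on the signed
right-minus-left stimulus difference (binned proportions are display-only);
pseudo-r² is 1 − log L_model / log L_null against an intercept-only model,
on held-out trials when provided. Weibull fits fix γ = 0.5 and the lapse at
its empirical estimate, with τ ∈ [1e-4, 1], β ∈ [0.1, 10], 5 seeded
restarts; a fit with no errors (or τ at a bound) is flagged, and a
threshold is non-measurable when τ + base exceeds the displayable range.
Weber slopes are closed-form log-log least squares over measurable JNDs.

## BOLD analysis

The FIR design is the exact Toeplitz-block construction: per condition, an
onset-indicator column shifted down k − 1 times (half-open response windows,
0-based volume indices, truncation at the series end). Deconvolution is
ordinary least squares; rank-deficient designs fall back to the
minimum-norm solution with a warning and a diagnostics flag, and the Gram
matrix is checked for off-diagonal mass (the multicollinearity check for
randomized designs). Scalar amplitudes are the closed-form projection
⟨fir, hrf⟩/⟨hrf, hrf⟩ onto the unit-peak canonical HRF. Gain/offset fits
hold σ and κ at their passive values so each task contributes exactly three
free parameters (α_con, α_coh, α_task — six per area); with the shapes
fixed the model is linear in those parameters and the least-squares solution
is exact, which is why noiseless recovery is tested at 1e-6. Trials are
binned at the nearest base strength before condition assignment; the two
hemisphere amplitude tables per area are averaged (stimuli drive
contralateral cortex, and both hemifields share base strengths).

## Model comparison

Ten-fold cross-validation with deterministic fold assignment stratified by
task (each fold contains both tasks); held-out Bernoulli log-likelihoods in
natural log are summed across folds, differences between models are the
likelihood-ratio statistic, and Tjur's CD is computed on the pooled held-out
predictions. No AIC/BIC correction is applied — cross-validation already
penalizes extra parameters, which is the mechanism by which spurious
stay/switch parameters fail to improve held-out likelihood.

## Problem sizes

Default test and demonstration sizes are chosen to make the statistical
checks decisive at interactive run times: 4,000-trial sessions for
parameter recovery and model selection (10 simulated observers), 500-trial
staircases (accuracy scored over trials 201–500, 10 seeds), 10⁶-draw
Monte-Carlo oracles for choice probabilities, and ~540-trial scan sessions
(≈17 repeats per condition, ≈8,800 volumes) for the deconvolution
round-trip and window-length checks.

## Known limitations

* Readout weights trade off exactly against a global response rescaling
  (the implied-noise degeneracy); only the products βR are identified.
* The Poisson variant's σ² uses responses including α_task, so additive
  offsets do not cancel there — a modelling choice, tested explicitly.
* The catch-trial working-memory cost is applied as a scalar on the
  required readout difference; no decay dynamics are modelled.
* PEST sustains accuracy slightly below its nominal target on steep
  psychometric functions (≈81% at a nominal 82% for the standard synthetic
  observer) because steps overshoot symmetrically on a bounded level set;
  this bias is well inside the tolerance used anywhere the target enters.
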