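# Methods

This note documents the models, the numerical choices, and what the
synthetic observers do and do not emulate.

## Signal detection (digit detection task)

Equal-variance Gaussian SDT: d′ = Φ⁻¹(H) − Φ⁻¹(F),
c = −(Φ⁻¹(H) + Φ⁻¹(F))/2, computed separately per value location from the
probed-disc responses.  Extreme rates use the log-linear correction
(0.5 added to each cell, 1 to each denominator); the correction can also be
applied unconditionally.  No unequal-variance or ROC extensions.

**Gaze residualization.**  d′ is regressed (OLS with intercept) on the mean
vertical saccade endpoint separately per location; the location comparison
is repeated on the residuals, and a reduction test runs a one-sample t on
the per-participant difference between the raw and the residual d′
contrast.  Because each per-location OLS forces its residuals to mean zero,
the residual comparison is centred at zero by construction; the informative
quantity is the reduction term, whose variance comes from the
slope-difference × endpoint spread.  With near-identical intercepts the
reduction test numerically approaches the endpoint test — which is exactly
the behavior the design predicts when gaze fully mediates the sensitivity
difference.  t statistics from this term can be very large when the two
location slopes are similar; Bayes factors therefore saturate at |t| = 37
(beyond which they are astronomically decisive and scipy's noncentral-t
machinery is unreliable).

## QUEST staircase

Discretized Bayesian threshold estimation in log10 Michelson contrast.
Prior: Gaussian centred at log10(0.2) with sd 0.3 — the printed "sd = 0.3"
is ambiguous between linear and log units; log units (the procedure's
native space) were chosen.  Likelihood: Watson–Pelli Weibull with β = 3.5,
guess γ = 0.5 (2AFC orientation discrimination), lapse δ = 0.02; none of
these are stated by the design, so conventional 2AFC values are used.
Placement and readout are both the posterior mean mapped to linear
contrast, clamped to the stimulus range [0.01, 0.9]; the grid spans the
clamp widened by three prior sds (300 points; refining 10× moves the
estimate by < 10⁻³).  Self-consistency: against an observer with the
assumed shape, 50-trial runs recover a 0.15 threshold with |bias| < 0.02.

The attentional imbalance (M_low − M_high)/(M_low + M_high) is used instead
of a raw threshold difference because posterior-mean thresholds are
positively skewed across observers.

## Psychometric fitting

Cumulative Gaussian with guess/lapse asymptotes bounded in [0, 0.1], fit by
penalized ML (Beta(1,19) priors on γ and λ rescaled to [0, 0.1]) with five
deterministic starts for L-BFGS-B.  The PSE is defined as μ — the 50% point
of the *unscaled* sigmoid — making it invariant under lapses and robust to
asymmetric asymptotes.  Degenerate data (all-identical responses, no level
dependence) return `converged=False` with diagnostics; a fit whose σ lands
on its bounds is likewise flagged rather than silently returned.  An
optional parametric bootstrap supplies a PSE CI.  The MLE is validated in
the tests against an exhaustive (μ, σ) grid search (Δloglik < 10⁻⁴).

**Bias indices.**  With o1/o2 the fits for standard-first/standard-second
trials, the index is s·[(PSE_o1,biased − PSE_o2,biased) −
(PSE_o1,unbiased − PSE_o2,unbiased)], s = +1 if the first interval is
rewarded and −1 otherwise, so positive always means favoring the rewarded
stimulus.  For the generating observer this index equals exactly
2·response_bias (reports only) or 2·perceptual_bias (both readouts) — the
closed form used in the recovery tests.

## Pursuit signal processing

Velocity = central difference of 2nd-order zero-phase Butterworth-filtered
position (30 Hz), filtered again at 40 Hz.  The order/cutoffs are not
specified by the design; these are standard in the pursuit literature.
Saccades are detected with velocity > 30 deg/s AND within-event
acceleration > 8000 deg/s² (tracker-parser cognitive defaults), events
< 20 ms apart merged.  Detection runs on a *lighter* 60/80 Hz velocity
trace: the 30/40 Hz analysis filters smear small catch-up saccades'
accelerations below 8000 deg/s², so events are located as a tracker parser
would on raw data and then excised (±10 ms padding, linear interpolation)
from the analysis trace.  Pursuit velocity is the mean of the desaccaded
trace over the half-open window [onset+250, onset+500) ms; windows with
> 50% interpolated samples carry a low-quality flag.  Oculometric
decisions ("comparison pursued faster") break exact ties — which occur
only with noise-free synthetic input — with a seeded fair coin.

The saccade endpoint of the digit task is the landing position of the
first saccade crossing the vertical midline (the alternative —
post-saccadic fixation centroid — was not chosen; see Limitations).

## Permutation inference

Cluster test: per-sample paired t between condition time courses; the
cluster-forming threshold is the pointwise two-sided t at α_cf = 0.05
(exposed as a parameter — no threshold is prescribed by the design);
clusters are maximal sign-consistent suprathreshold runs, mass = Σt.  The
permutation distribution flips the condition assignment within participant
(sign flips of difference curves, vectorized with a cumulative-sum-with-
reset scan), the critical value is the 95th percentile of permuted
strongest clusters, and p = (b+1)/(B+1) so p ∈ (0, 1].  Reversals are
averaged within participant before the group test — the participant is the
exchangeable unit; reversals whose ±1000 ms window crosses a recording
edge are dropped and counted.  Fixation tests permute labels within
participant and use either the centroid distance or the difference of mean
distances to a diagnostic region.  Calibration: both tests reject at
3–7% under exchangeable nulls (1000 simulations, asserted in the tests).

## Group statistics

t-tests (one-sample/paired/independent) report Cohen's d (mean/sd, or
pooled-sd) with a 95% CI from noncentral-t inversion, and a JZS Bayes
factor: Cauchy(0, √2/2) prior on the standardized effect, marginal
likelihood by adaptive quadrature of the noncentral-t density in a
log-rescaled form (validated against the inverse-gamma-parametrized Rouder
integral to 0.1%).  One-sided tests truncate the prior to the hypothesized
half-line.  Wilcoxon signed-rank drops zero differences and enumerates the
exact null for n ≤ 25.  C-RAI scoring: six 4-item subscale means;
autonomous/controlled composites are means of subscale means by default
(sums available), self-concordance their difference, z-standardized across
the sample; Cronbach's α for reliability.

## Synthetic observers

The generators reproduce the printed designs exactly — digit task: 500
trials = 400 detection + 100 attention (50/location), interleaved; speed
task: 2 blocks × 216 trials (36 each of 7.5/8/8.5 deg/s, 18 of the rest,
crossed with order and both intervals' durations from {540, 720, 900} ms);
ambiguous viewing: 34 three-phase trials with a 2500 ms instructed hold;
forced fixation: 40 illusion trials (4 stimuli × 10, 5 per fixation) and
280 composite trials per fixation (40 × five difficult proportions,
20 × four easy).  One session seed expands into per-purpose substreams so
reordering consumers never breaks reproducibility.

Generator internals the designs leave open are stand-ins chosen once at
field-typical values:

* digits: discretized normal over {1..9}\{5} centred at 7 (high value) or
  3, spread solved numerically so P(digit > 5) = 0.75 exactly (0.25 by the
  symmetry of the digit set);
* detection behavior: d′ decays linearly with endpoint-to-target distance
  (slope an observer parameter, matching the observed linear
  endpoint–sensitivity regressions); criterion carries the
  value-conditioned shift; defaults (−0.24/−0.09, endpoint bias 0.3°,
  between-participant spreads) follow the reported group means/SDs;
* pursuit: latency 140 ms, exponential rise τ = 60 ms, gain 0.95, white
  motor noise 4 deg/s; shared sensory noise 1 deg/s per interval feeds
  both pursuit and report (this shared signal is what couples the two
  readouts in the unbiased block); catch-up saccades are 16 ms
  raised-cosine velocity pulses triggered by > 0.5° positional error with
  a 1/catchup_rate refractory and a 0.8° predictive overshoot — sized so
  their kinematics fall in the range real catch-up saccades occupy;
* percept reversals: two-state semi-Markov with exponential dwells
  (0.25 reversals/s); gaze relaxes toward the current percept's diagnostic
  point with τ = 200 ms plus AR(1) fixation jitter, and the gaze target
  switches `gaze_lead` (300 ms) before the report flips;
* forced fixation: Bernoulli responses from a cumulative Gaussian in
  face-proportion with fixation-conditioned PSEs (0.43/0.49, σ = 0.12);
  illusion reports are congruent with the fixated region with probability
  0.65.

What the generators do **not** emulate: pixel-level stimuli, pupil or
binocular signals, blinks (the ASC reader handles gaps, the generators do
not produce them), drift/noise nonstationarities, learning or fatigue, and
any correlation between motivation-questionnaire scores and task behavior.
Passing recovery tests therefore shows the analysis chain is correct and
well-calibrated under the stated generative assumptions — not that those
assumptions exhaust real oculomotor data.

## Problem sizes

The test suite runs the full trace pipeline at 50 simulated participants
for the dissociation recovery, 60 for criterion recovery, 24 sessions at
the printed 560-trial counts for the PSE gap, 500 seeded staircases, and
1000 null simulations per permutation test; the acceptance script uses the
study's sample sizes (60/20/16/24).  The acceptance cohorts set the
generative report bias to 0.875 deg/s so the expected index (1.75 deg/s)
matches the reported group effect.

## Known limitations

* The reduction test for the residualization analysis is an
  interpretation; the original analysis is not spelled out.
* Whether the per-participant quantity behind the reported
  pursuit–perception agreement is the PSE is assumed, not asserted.
* The endpoint definition (first midline-crossing saccade's landing) is
  one of two defensible readings.
* The OSF data layout of the original study is unknown; `traceio` reads a
  documented ASC-like dialect and versioned CSVs rather than a hard-coded
  adapter.
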