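# Methods

`revlearn` implements an analysis pipeline for probabilistic reversal
learning under volatility: simulation of the task and of learning agents,
hierarchical Bayesian modelling of choice behaviour, non-parametric
behavioural statistics, and deconvolution of oscillatory neural responses to
model-derived regressors.  This note documents the models, the numerical
choices, and what the synthetic data do and do not establish.

## Task model

Two stimuli carry reciprocal reward probabilities (p, 1−p).  A session has
two blocks of 160 trials; within each block the contingency is piecewise
constant with five segments, one per mapping in {0.9, 0.1, 0.7, 0.3, 0.5},
in an order permuted independently per block, each segment lasting 26–38
trials.  Segment lengths are drawn uniformly on [26, 38] and repaired to sum
to 160 by ±1 adjustments of randomly chosen segments that can move without
leaving the bounds; this stays unbiased within the stated constraints.
Because block orders are independent, the mapping can repeat across the
block boundary, so a session contains 8 or 9 contingency changes.  Event
timing (1300 ± 125 ms response window, 1000 ± 200 ms choice highlight,
1900 ± 100 ms outcome, 1750 ± 250 ms inter-trial interval) is jittered
uniformly within the stated ranges; the distribution family is a design
choice, as only the ranges are specified by the task.  The oracle
("ceiling") win rate of a schedule is the mean over trials of max(p, 1−p);
for this contingency set its ensemble mean is 0.74 and its constrained
maximum — longest segments on the 0.9/0.1 mappings, shortest on 0.5 —
is 0.7625.  Points convert to payment as points/6 + 400 currency units.

## Learning model: the binary Hierarchical Gaussian Filter

Level 2 tracks the log-odds tendency x2 of the binary outcome; level 3
tracks the log-volatility x3 of x2.  Both evolve as Gaussian random walks,
coupled through the variance of the level-2 walk, exp(κ·x3 + ω2).  Filtering
a binary input sequence u gives trial-wise posterior means and variances
(μ2, σ2, μ3, σ3).  Per trial:

- prediction: μ̂2 = μ2 (previous posterior), μ̂1 = logistic(μ̂2),
  environmental uncertainty v = exp(κ·μ3 + ω2);
- level 2: predicted precision π̂2 = 1/(σ2 + v); posterior precision adds the
  Bernoulli information, π2 = π̂2 + μ̂1(1−μ̂1); the precision-weighted
  prediction error is ε2 = σ2·δ1 with δ1 = u − μ̂1, and μ2 ← μ̂2 + ε2;
- level 3: with weight w = v·π̂2 and volatility prediction error
  δ2 = (σ2 + ε2²)·π̂2 − 1, the posterior precision is
  π3 = 1/(σ3 + exp(ω3)) + ½κ²w(w + (2w−1)δ2) and μ3 ← μ̂3 + ε3 with
  ε3 = ½σ3κwδ2.

A non-positive posterior precision anywhere makes the trajectory invalid;
filtering raises an error carrying the trial index, which the fitting layer
converts to a −∞ log-likelihood.  The two-level variant freezes level 3 at
its initial values.  Missing inputs (timeouts) run the prediction step only
and carry the posterior forward; their prediction errors are NaN and they
contribute nothing to likelihoods.  κ is fixed at 1 throughout; (μ2⁽⁰⁾,
σ2⁽⁰⁾) are fixed at (0, 1).

## Response models

All three candidate models map the predictive probability m = μ̂1 to choice
probability through the unit-square sigmoid
p(y=1) = m^ζ / (m^ζ + (1−m)^ζ).  The 2- and 3-level fixed-noise models
estimate a constant inverse decision noise ζ; the volatility-coupled model
(hgf3_mu3) sets ζ_k = exp(−μ3⁽ᵏ⁻¹⁾), so a higher predicted log-volatility
makes choices more stochastic.  With μ3 frozen at a constant c the
volatility-coupled likelihood equals the fixed-ζ likelihood at ζ = e^(−c)
(tested).  Choice probabilities are computed in logit space; predictions are
kept strictly inside (0, 1) so likelihoods stay finite.

## Inversion and model selection

Each model is inverted per subject by maximum-a-posteriori estimation in an
unconstrained space (identity transforms for ω2, ω3, μ3⁽⁰⁾; log for ζ and
σ3⁽⁰⁾) with Gaussian priors.  Default priors are broad TAPAS-style
surrogates: ω2 ~ N(−3, 16), ω3 ~ N(−6, 16), log ζ ~ N(log 48, 1),
μ3⁽⁰⁾ ~ N(1, 1), log σ3⁽⁰⁾ ~ N(0, 1).  Free parameters per model —
hgf2: (ω2, ζ); hgf3: (ω2, ω3, ζ); hgf3_mu3: (ω2, ω3, μ3⁽⁰⁾, σ3⁽⁰⁾).
Optimisation is multi-start quasi-Newton (L-BFGS-B; 8 restarts by default,
start points = prior mean plus seeded Gaussian perturbations scaled by the
prior SD); invalid trajectories score a large penalty.  The log-model
evidence is the Laplace approximation at the MAP: log joint + d/2·log 2π +
½·log det Σ, with Σ from a symmetrised central-difference Hessian (relative
step 1e−4, eigenvalues floored at 1e−10).  Laplace at the MAP is used as the
standard MAP-consistent surrogate for a full variational free energy; only
LME differences enter model selection.

Random-effects Bayesian model selection treats models as random effects:
starting from a uniform Dirichlet prior (α0 = 1), per-subject posterior
model probabilities g_nk ∝ exp(LME_nk + ψ(α_k) − ψ(Σα)) and the Dirichlet
concentration α = α0 + Σ_n g_n are iterated to convergence.  Expected
frequencies are α/Σα; exceedance probabilities are Monte-Carlo estimates
(10⁶ Dirichlet draws, seeded).  The procedure is invariant to adding a
per-subject constant to the LMEs.  When one model dominates every one of 39
subjects, α = (40, 1, 1) gives expected frequency 40/42 ≈ 0.952 and
exceedance ≈ 1 — the configuration the synthetic model-selection experiment
reproduces.

Parameter recovery (simulate → refit → correlate) draws generating
parameters from ω2 ~ N(−3, 1), ω3 ~ N(−6, 1), μ3⁽⁰⁾ ~ N(1, 0.5); draws whose
trajectories are invalid are rejected and redrawn, since only realisable
behaviour is ever fitted.  At 50 replicates of 320 trials, recovery
correlations are ≈ 0.8 for ω2 and ≈ 0.85 for μ3⁽⁰⁾ against ≈ 0.35 for ω3;
the third-level tonic volatility is poorly identified, as expected from the
weak constraint 320 binary trials place on it.

## Synthetic cohorts

The default two-group cohort has 20 "low" and 19 "high" subjects, all
generated from the volatility-coupled model with independent schedules.  The
groups share ω2 ~ N(−3, 0.3) and ω3 ~ N(−6, 0.5); the high group's initial
log-volatility expectation is μ3⁽⁰⁾ ~ N(1, 0.25) against N(0, 0.25) in the
low group.  Through the coupling exp(κμ3 + ω2) this single difference
produces faster updating, larger informational and environmental
uncertainty, and — through ζ_k = exp(−μ3) — noisier, more switch-prone
choices in the high group, so the cohort reproduces the qualitative
behavioural signature of interest (higher lose-shift and switch rates) from
one generative difference.  The spread values are chosen to give clear but
overlapping group distributions at n ≈ 20 per group.

## Behavioural statistics

Win-stay and lose-shift rates are normalised per outcome type (stays after
wins / wins; shifts after losses / losses); the last trial contributes no
pair and pairs involving a missing response are excluded.  No-response
trials count as losses in the win-rate denominator by default (they score no
points); this is configurable.  Group comparisons use label-permutation
tests (difference of means, two-sided p = 2·min(p_low, p_high) with add-one
correction, capped at 1) and sign-flip tests for paired differences.  Effect
sizes are probabilities of superiority: Δ = P(a>b) + ½P(a=b) by full
pairwise enumeration for independent samples, Δ_dep = P(d>0) + ½P(d=0) for
paired differences, both with seeded percentile-bootstrap confidence
intervals.  The 2×2 mixed design (group between, block within) uses
synchronised rearrangements: group labels are permuted over subject means
(group main effect) and over within-subject differences (interaction), and
block labels are sign-flipped within subjects (block main effect) — each
test rearranges only the factor under test.  Multiplicity is controlled with
the adaptive two-stage linear step-up FDR procedure (stage 1 at q/(1+q)
estimates the number of true nulls; stage 2 rescales), delegated to
statsmodels' two-stage Benjamini–Hochberg and verified against a hand-stepped
execution.  Spearman correlations use midranks with a permutation p-value.

## Time-frequency convolution GLM

Source-level series are transformed with Morlet wavelets in 2-Hz bins
(8–30 Hz at 5 cycles; 32–100 Hz at 7 cycles) and converted from power to
amplitude by a square root, which brings the residuals closer to the GLM's
error assumptions.  The design convolves per-event-type input functions
(impulses carrying 1 for discrete events or the trial's regressor value for
parametric events) with a Fourier basis of order m over the peri-event
window (default m = 20 over [−0.5, 1.8] s, i.e. 40 basis functions
resolving envelope modulations up to 20/2.3 ≈ 8.7 Hz; order 40 gives
2300/40 = 57.5 ms resolution).  OLS per frequency uses a pseudoinverse with
cutoff 1e−10 of the largest singular value; a rank-deficient design raises
an error listing the collinear columns.  Response images are R_i = B·β_i.

The Fourier basis is zero-mean over the window, so a response image is
defined up to a window constant that the single global intercept absorbs;
baseline normalisation (subtract mean, divide by SD of a pre-event interval,
default [−0.3, −0.05] s, per frequency) removes the ambiguity before any
statistics.  An optional per-regressor DC column (`dc=True`) recovers
responses in absolute units instead; it is off by default to match the
2m-function convention, and the rank check guards the degenerate case where
event boxcars tile the series.  Parametric HGF regressors (|ε2|, σ2, σ3
outcome-locked; |μ̂2| stimulus-locked; signs of ε2 and μ̂2 are arbitrary, so
absolute values are used) are screened for pairwise collinearity at
|r| ≥ 0.2; ε3 is excluded when collinear with |ε2|, which simulated
trajectories always produce, as both are driven by the same outcome
prediction errors.

The synthetic neural generator emits fixed-frequency carriers whose Hann
envelope around events of one type is scaled by 1 + Σ gain·regressor, plus
white Gaussian noise, and returns the injected envelopes as ground truth.
It deliberately omits 1/f background spectra, sensor physics, and
inter-regional structure; recovery results on it validate the linear
deconvolution algebra and design resolution, not robustness to realistic
MEG noise.  The generator and GLM operate on a continuous series; epoched
recordings should be concatenated upstream, and the fit accepts a sample
mask to exclude samples (e.g. near epoch boundaries).

## Cluster-based permutation statistics

Group contrasts of (baseline-normalised) response images use per-pixel
two-sample t-tests, cluster formation at the two-sided t critical value for
p = 0.05 (configurable; a conventional default, as the threshold itself only
shapes sensitivity, not validity), adjacency 8-connected within a label's
time-frequency grid and never across labels, cluster mass = summed t, and a
group-label permutation null of the maximum mass per sign with FWER 0.025
per tail.  Analysis can be restricted to a temporal window of interest
before clustering.  Observed t-maps and dominant cluster masses match MNE's
cluster permutation test under the same adjacency on shared data.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; one root seed fans out
via `numpy.random.SeedSequence` spawning.  The validation suite uses 400
schedules for ensemble statistics, a 39-subject synthetic cohort with 4
optimiser restarts per fit for model selection, 50 recovery replicates,
2000 simulated nulls for permutation-test calibration (Kolmogorov–Smirnov
on the p-value distribution), 2000 for the factorial rates, and 300 for
cluster FWER; these sizes give binomial/KS resolution comfortably inside
the asserted bands.  The acceptance script uses 1000 schedules and the full
39-subject experiment.

## Known limitations

- The Laplace LME penalises complexity more crudely than the full
  variational free energy; it is adequate for the large per-subject LME
  gaps seen here but could blur selection between nearly equivalent models.
- ω3 is structurally poorly identified from 320 binary trials; its
  posterior is prior-dominated.
- Prior settings are surrogate defaults in the TAPAS style, not transcribed
  study values; results that depend on exact prior means (e.g. absolute
  parameter estimates) should be read accordingly.
- The synthetic neural model validates deconvolution algebra only; no claim
  is made about detectability under realistic MEG noise or source leakage.
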