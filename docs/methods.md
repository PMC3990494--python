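# Methods

## The accumulation-to-bound model of effort allocation

A single latent variable, *cost evidence*, rises linearly during effort
with slope `Se` (cost-evidence units per second) and falls during rest
with slope `Sr`, between a lower bound (triggering effort resumption) and
an upper bound (triggering effort cessation) separated by an amplitude
`A`.  Because the dynamics are linear, epoch durations are deterministic
ratios:

    Te = A / Se        Tr = A / Sr

A trial starts at the lower bound with an effort epoch (the incentive has
just been displayed and no cost has accumulated) and the alternation is
truncated at the trial length (30 s in the free-allocation tasks); the
cut-short final epoch is flagged and excluded from fitting, as is each
trial's final rest epoch, which is shaped by the approaching trial end
rather than by dissipation.

Experimental factors modulate the latent parameters around baseline
values, linearly in the incentive `I` and actual difficulty `Da`, and —
in the hyperbolic family — with cued difficulty `Dc` acting as a
hyperbolic discounter of the incentive term:

    P = mean + w_I * I / (1 + k * Dc) + w_Da * Da        (hyperbolic)
    P = mean + w_I * I + w_Da * Da + w_Dc * Dc           (linear)

Baselines (intercepts) are always present; a pure-modulation variant is
expressed by setting a baseline to zero, subject to overall positivity.
Non-positive latent parameters raise an invalid-region error rather than
being clamped, so fitters see a clean penalty surface.

## Model space and producibility pruning

A model is a binary pattern saying which factors may modulate which of
(A, Se, Sr): 2^6 = 64 configurations for two factors, 2^9 = 512 for
three; in the hyperbolic family a cued-difficulty (denominator) flag
without the incentive (numerator) flag on the same parameter is inert and
excluded, leaving 6 valid per-parameter combinations (216 overall).

Configurations that cannot reproduce the observed significant effects for
any signed weights are pruned by two rules:

1. *Pathway rule* — a factor can move `Te` only through `A` or `Se`, and
   `Tr` only through `A` or `Sr`.
2. *Sign rule* — opposite-signed effects on `Te` and `Tr` require the
   factor to touch at least two distinct latent parameters; an `A`-only
   pathway moves both durations in the same direction because they share
   the numerator.

With the observed requirement sets (incentive: opposite-signed effects on
effort and rest; actual difficulty: an effort-duration effect; cued
difficulty: a rest-duration effect), the pruned spaces contain 24
(implicit), 16 (explicit linear), 144 (dissociation linear) and 78
(hyperbolic, shared by the explicit and dissociation tasks) models.  A
property test validates the rules against a brute-force oracle that
samples random signed weights and numerically checks achievable sign
patterns.

## Per-subject estimation and model evidence

The forward model is deterministic; each non-truncated epoch duration is
treated as Gaussian around its condition prediction, with residual
variance profiled separately for effort and rest epochs (the profiled
likelihood depends on cell counts, means and within-cell sums of squares
only, so fitting cost is independent of epoch count).

Multiplying `A`, `Se`, `Sr` and all modulation weights by a common
constant leaves every prediction unchanged, so the baseline amplitude is
fixed at `A = 1` and all other quantities are estimated relative to it.
Recovery is therefore defined up to a positive per-subject scale; signs
and correlations, which the recovery tests assert, are scale-invariant.

Priors: modulation weights N(0, 1); slope baselines log-parameterised
(positive by construction) with N(center, 1) priors centred on the
data-implied values `log(1/mean duration)`; hyperbolic discount rates
log-parameterised with N(0, 1) priors.  Optimisation is quasi-Newton
(L-BFGS-B) from 8 prior-drawn multi-starts by default (fewer in
scaled-down studies), ties broken by the smaller coefficient norm.  Model
evidence is the Laplace free energy at the posterior mode,

    log p(y|m) ~ log p(y, theta_hat) + (d/2) log 2pi - (1/2) log det H,

with H the finite-difference Hessian of the negative log joint.  Epochs
may be fit raw (default) or as condition-cell means; the profiled-
likelihood algebra makes the two equivalent for the Gaussian model.

## Group Bayesian model selection

Random-effects selection treats each subject's generating model as a
draw from a multinomial with Dirichlet-distributed frequencies (uniform
prior, alpha = 1 per model).  A Gibbs sampler alternates subject labels
(evidence-weighted frequencies) and frequencies (Dirichlet posterior of
label counts); 5,000 sweeps with 1,000 burn-in, Rao-Blackwellised label
averaging, and 10^5 Dirichlet draws from the final concentration for the
exceedance probabilities (argmax ties split equally; Monte-Carlo error
below 0.005).  Family inference places prior mass uniformly over families
(per-model alpha = 1 / family size) and aggregates frequency draws.  The
sampler is validated against exhaustive label-enumeration plus simplex
quadrature at K = 2, n = 3.

## Cost introspection

Cost evidence over mean-normalised difficulty `d` and duration `t`:

    C = b0 + b1 * d^l1 + b2 * t^l2 + b3 * d^l1 * t^l2

Three binary choices — main effects (b1, b2), interaction (b3), free
exponents versus l = 1 — give eight models (the two constant variants are
mathematically identical and both kept).  Ratings (mapped to [0, 1] from
the 50-step scale) are fit directly; stop probabilities — the empirical
CDF of non-truncated effort durations per difficulty, on a common
duration grid ending at the longest observed epoch — through an
unparameterised sigmoid.  The exponents are shared between the main and
interaction terms, which is the only reading consistent with the three
reduction statements (b3 = 0 additive, b1 = b2 = 0 interactive, l = 1
linear).

Exponent priors are deliberately tight: log l ~ N(0, 0.1^2).  On the
narrow factorial range (d within ±20%, t within ±40% of their means) the
pure-interaction model with free exponents can mimic *any* additive
surface (the exponent ratio tracks the weight ratio and the residual
cross-term is far below realistic rating noise), and with wide exponent
priors the Laplace evidence rewards the mimic because its weakly
identified exponents are charged less than the additive model's
well-identified betas.  The tight prior expresses that power distortions
of a rating scale much beyond ±20% are implausible, and restores a
well-posed comparison; a recovery analysis confirmed that genuinely
nonlinear data (exponents near 1.6) still select the nonlinear variants.
Because the linear additive model and its free-exponent twin are nested
and identical at the additive truth, their evidences tie intrinsically
and group selection splits mass between them; recovery claims are
therefore stated at the level of model structure (main effects versus
interaction).

The CES surface `offset + scale * (alpha d^delta + (1-alpha) t^delta)^(1/delta)`
characterises curvature: delta = 1 is exactly the additive surface,
delta < 1 gives iso-cost contours convex toward the origin.  delta is
estimated on the log scale within [0.05, 20] (boundary fits flagged)
under a log delta ~ N(0, 0.5^2) prior centred on the additive point:
the curvature enters only through a second-order cross term that sits
below per-subject noise at the design's scale, and the unregularised
estimator piles up at the bounds with a downward median bias.  Centring
on delta = 1 is the conservative choice — it biases *against* finding
curvature — and multiplicative ground truth still yields group medians
near 0.6.  Confidence intervals by residual bootstrap on request.
Noiseless data recover delta to three decimals.

## Saturation analysis

Three transfer functions from imposed to observed durations: linear,
bounded linear `y = b1 + b2 * min(x, x0)` with a free breakpoint, and
exponential saturation `y = gamma + (b1 - gamma) exp(-b2 x)`.  All three
are fit by the same machinery — data standardised internally, standard-
normal priors, profiled residual variance, multi-start quasi-Newton,
Laplace evidence — with no model-specific breakpoint grid search.  This
procedural parity is what makes the white-noise simulation meaningful:
with noisy data the kinked bounded-linear likelihood is hard for a
generic optimiser while the smooth exponential is robust, so simulation-
averaged evidence favours the exponential at realistic noise and swings
back to the generating bounded-linear model as noise shrinks — the
calibration argument for including the exponential model when analysing
observed data.

The synthetic cohort for this study uses bounded-linear truths around
(intercept 3 s, slope 0.5, breakpoint 6 s, residual sd 1.2 s, 15%
between-subject jitter), i.e. second efforts growing with imposed rest up
to a plateau, at the variable-rest task's quantile grid (a 75/25 Gaussian
mixture N(3, 2)/N(10, 2) truncated at 1 s, 37 equal-count bins, last bin
dropped).

## Synthetic data

Generators are pure functions of (design, truth, seed) and emulate the
task designs: 3 incentives x 3 difficulties, 8 sessions x 9 trials,
30-s trials (implicit/explicit); 2 x 2 x 2 with cues valid in half the
cells and no identical consecutive cue pair (dissociation, by rejection
sampling); 36 imposed durations balanced across sessions by the
every-4th-point scheme (adaptation); 3 x 7 x 7 = 147 cells, each
presented once, sessions exactly balanced in incentive and difficulty
with durations rotated (cost rating).

Default generating coefficients follow the winning configuration
(amplitude up with incentive, accumulation slope up with actual
difficulty, dissipation slope up with incentive and hyperbolically
discounted by cued difficulty) at magnitudes giving ~5–8 s efforts and
~3–5 s rests — a handful of alternations per trial.  Epoch noise is
additive Gaussian truncated at 0.2 s, default sd 20% of the mean
predicted duration; between-subject heterogeneity is 20% Gaussian jitter
on every nonzero coefficient (re-drawn if a condition cell would leave
the valid parameter region).  The additive rating truth uses asymmetric
weights (difficulty 0.28, duration 0.14 on the unit rating scale),
mirroring the roughly two-to-one difficulty/duration asymmetry of rated
exhaustion; a symmetric choice would make the pure-interaction model an
exact additive mimic and the comparison degenerate.  Rating noise
defaults to 0.05 of the scale.

What the generators do *not* emulate: reaction-time initiation delays,
within-epoch force dynamics beyond ramp-plateau-ramp traces, slow fatigue
accumulating across trials, and non-Gaussian rating noise.  Passing
recovery tests therefore show that the inference machinery is correct
and well calibrated under the model's own assumptions at realistic noise,
not that real grip-force data satisfy those assumptions.

## Force-trace preprocessing

Maximal force: mean of the calibration samples in the last half of the
squeeze window at or above the whole-window median (the simplified
variant averages the whole fixed 5-s window).  Non-strict exceedance is
used so a constant squeeze yields its own level; the error branch (last
half entirely below the median) remains reachable.

Off-line epoch detection applies two joint criteria — derivative
beyond one standard deviation of the whole-trial derivative series, and
force below (onset) or above (offset) half the maximal force — to a
lightly smoothed trace (50-ms moving average by default; the rule on raw
sampled noise is degenerate).  Onsets/offsets are placed at the start of
the rising/falling high-derivative run adjoining each above-half-max
region; half-max ties resolve toward continuing the current epoch,
avoiding single-sample epochs.  The derivative sd is computed per trial
(the only whole-trial statistic available off-line; whether the original
analysis pooled across a session is not recoverable).  The first rest
period runs from trial start to the first onset.  Round-trip tests
against the trace generator recover all effort boundaries within the
smoothing window at trace noise up to 0.02.

## Statistics layer

Subject-level multiple regressions z-score all regressors (and the
response), so betas are standardised effect sizes; interaction columns
are products of z-scored columns, re-z-scored.  Orthogonalised
covariates (e.g. residual initiation delay) are residualised against the
listed regressors before z-scoring.  Group inference is a two-sided
one-sample t-test of per-subject betas; paired contrasts can instead use
the exhaustive 2^n sign-flip permutation distribution of the paired t
statistic (exact and deterministic up to 2^15 flips; seeded random
subsets beyond).  No multiple-testing correction is applied.

## Problem sizes and numerical choices

Recovery studies in the test suite run at documented desk scales: 15
subjects for parameter recovery (20 seeds), 12 subjects for model
recovery over the 24-model space (5 seeds, 2 optimisation starts), 12
subjects x 100 simulations x 3 noise scales for the saturation study, 18
rating / 12 stop-curve subjects for the cost dissociation with 20-seed
CES medians.  Profiled residual variances are floored at 1e-8 (duration
fits) / 1e-10 (cost fits); Hessians are symmetrised central differences
with eigenvalues floored at 1e-8; a fit with non-finite evidence is
flagged with worst-case evidence rather than raised.  All randomness is
generator-seeded; every pipeline stage requires an explicit seed.

## Known limitations

The Laplace evidence is a local approximation; for kinked
(bounded-linear) or boundary (delta, k) modes it inherits the usual
caveats, which is precisely the behaviour the saturation noise study
quantifies.  The hyperbolic discount rate is constrained positive.
Protected exceedance probabilities and fixed-effects group inference are
not implemented.  Real-data effect sizes, p-values and ef/xp values from
the original studies are not reproducible here because the subject data
are not public; the pipeline's claims are about recovery of known ground
truth under the stated generative conditions.
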