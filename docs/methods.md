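# Methods

## The model

`sleepddm` analyzes two-choice lexical decisions (word vs pseudoword,
signalled by facial-muscle contractions) made across states of
consciousness: wake, N1, N2, REM and lucid REM. The core model is the
two-boundary Wiener drift-diffusion process with unit diffusion
coefficient. Evidence X(t) starts at `z·a`, drifts at rate `v`, and is
absorbed at 0 or `a`; observed RT is the first-passage time plus a
non-decision latency `t`. The likelihood is the Wiener first-passage-time
(WFPT) density, evaluated by the standard pair of series expansions
(small-time and large-time), switched by the usual truncation-error
criterion with default tolerance 1e-6. All parameter magnitudes are on the
unit-diffusion scale, on which the threshold grand mean sits near 2.54.

Boundaries are accuracy-coded: the upper boundary is the correct response,
so stimulus and stage effects load on the parameters rather than on
boundary identity. Per trial,

    v, a, t = β0j + β1j·Wordtype + β2j·Sleepstage + β3j·Wordtype×Sleepstage
    z       = β0j                                  (participant level)

with treatment coding (references: wake, pseudoword), subject-level
coefficients βj drawn from group-level normal distributions (mean μ,
spread σ), identity links, and a likelihood that returns −∞ for invalid
implied parameters (a ≤ 0, t < 0, t ≥ rt, z outside (0,1)). Inter-trial
variability parameters (sv, st, sz) are deliberately absent. Estimating z
at the participant level under accuracy coding means z > 0.5 is a
pre-decision bias toward the *correct* boundary; unusual, but it is the
structure this analysis chain is committed to, and it is noted here for
interpretation.

Four nested variants support model comparison: FULL (v, a, t all
stimulus × stage × interaction), MAIN_EFFECTS (no interactions), CONST_A
(threshold intercept-only) and CONST_T (non-decision time intercept-only).

## Sampler

PyMC-style NUTS is not applicable to the WFPT likelihood without custom
gradients, and the reference toolchain for this model family uses
coordinate-wise MCMC; the package therefore ships its own numba-compiled
adaptive Metropolis-within-Gibbs kernel:

* per-coordinate random-walk MH on every subject-level coefficient and on
  z, with proposal scales tuned during burn-in toward 44% acceptance;
* conjugate Gibbs updates for group means given subject coefficients, and
  log-scale MH for group spreads (half-normal priors);
* joint "shift" moves that translate one group mean together with all its
  subject coefficients — these cure the slow random-walk drift of the
  common level that centered hierarchies exhibit when per-subject data are
  weak;
* per-subject adaptive-covariance (Haario-style) block proposals over the
  full coefficient-plus-z vector, learned during burn-in and proposed at
  two scales — these traverse the v/a/t trade-off ridges within sparse
  condition cells that coordinate-wise updates cross only by diffusion.

Priors are weakly informative: group means normal(0, 5) for intercepts and
normal(0, 2) for effects; group spreads half-normal(1) and half-normal(0.5)
respectively; z bounded to (0.02, 0.98) with a truncated-normal population
distribution. All priors are configurable (`PriorConfig`).

Convergence is checked with rank-normalized split R-hat on the group-mean
nodes at the conventional 1.1 bar; failures set a flag on the fit and are
never silently dropped. Defaults follow the analysis protocol this package
reproduces: 10,000 sweeps per chain with 1,000 burn-in for main fits, two
chains. At the desk-scale validation protocol (2 × 3,000, burn-in 500) fits
on the hardest synthetic datasets can sit marginally above the bar on a few
nodes; validation reports therefore record the flags and pool flagged
iterations rather than excluding them, since excluding would leave too few
iterations to score.

DIC is mean deviance plus pD, with pD in the Spiegelhalter form (mean
deviance minus deviance at the posterior mean of the subject-level
parameters) and the variance form var(deviance)/2 as a fallback when the
plug-in deviance is undefined.

The trial sampler is Euler–Maruyama with dt = 1e-4 (configurable), which
doubles as the independent simulation oracle for the density; passages
slower than a 30 s horizon are truncated and flagged. The first-passage
engine is verified against the closed-form absorption probability, 
quadrature normalization of the density, a Kolmogorov–Smirnov comparison
of 1e5 sampled RTs with the analytic CDF (distance < 0.01), and a grid
MLE on 5e4 simulated trials that lands on the generating parameters.

## Behavioral mixed models

Trial-level accuracy is modelled with a Bernoulli family (logit link) and
RT with a shifted-lognormal family, both with stimulus × stage fixed
effects and participant random intercepts, fit by the same style of
adaptive MH kernel (4 chains × 5,000 sweeps, warmup 500, by default). The
lognormal shift δ is a single parameter shared across conditions within a
fit — the common convention — bounded by the smallest observed RT, with a
uniform prior on that range. Because δ trades off against the location
along a posterior ridge, the kernel includes a joint adaptive proposal
over (intercept, σ_log, δ); without it the shift's HDI under-covers. An
optional RT control model adds response accuracy as a fixed factor plus
the stimulus × accuracy × stage interaction. Cell means are reported on
both the link and the original scale (probability / seconds), the RT mean
as δ + exp(η + σ²/2) per draw.

## Synthetic studies: what the generator emulates

The generator reproduces the experiment's trial structure: a
narcolepsy-like cohort (27 participants, ~50 response trials each,
Poisson-varying, split over stage × stimulus cells by a multinomial with
weights wake .40 / N1 .20 / N2 .15 / REM .10 / lucid REM .15 and an even
word/pseudoword split) and a healthy-like cohort (21 participants, ~28
trials, wake .70 / N1 .18 / N2 .12, no REM states). The stage weights are
assumptions — the study's per-stage tables are not reproducible from the
text — and are configurable.

Default generating magnitudes are round, plausible values chosen once to
encode the study's qualitative findings rather than its unprinted fitted
posteriors: the word-vs-pseudoword drift advantage (+0.30) present in wake
shrinks in N1 (interaction −0.10), collapses in N2/REM (−0.25/−0.30) and
is restored in lucid REM (0); the decision threshold is elevated in lucid
REM (+0.458 against a wake baseline of 2.44, cell-averaged grand mean
≈ 2.54) with a null effect in N1; non-decision time lengthens with sleep
depth (+0.15 to +0.30 s). Under these values simulated studies show
overall accuracy in the mid-0.80s, graded down from wake to REM, and
right-skewed RTs of 1–3 s — the behavioral regime of the task. Subject
spreads are 0.3–0.4 for intercepts and 0.03–0.15 for effects.

Artifacts are planted independently per trial at the study's rates
(micro-arousals 13.6%/15%, single contractions 1.5%/0.6%, optional
non-responses), with order-aware planted counts returned so the exclusion
pipeline's per-rule tallies can be checked exactly.

What the generator does *not* emulate: EEG/EMG waveforms, session/block
structure, stimulus-level lexical covariates, response-omission patterns
that correlate with sleep depth, and any drift of parameters within a
session. Passing validation on these synthetic studies therefore
establishes that the *pipeline* is correct and identifiable at the study's
data volume — not that real sleep behavior obeys the model.

## Trial exclusions

Applied in a fixed order so tallies are unambiguous: (1) non-response
trials; (2) micro-arousal trials; (3) single muscle contractions (a valid
response requires at least two consecutive contractions); (4) stages
dropped per group (healthy-like: N3/REM/lucid REM; narcolepsy-like: N3);
(5) RT outside [0.69 s, 9.9 s], bounds inclusive; (6) robust RT outliers
within subject × stage × stimulus cells. The published rule "mean ± 2.5
MAD" mixes a mean center with a MAD scale; the default here is the
standard robust reading (center = median, scale = 1.4826 × MAD), with a
"literal" mode (center = mean, scale = raw MAD) selectable. Cells
with fewer than 4 trials skip the outlier rule (the MAD is degenerate
there), and the outlier pass iterates to a fixed point within each cell so
the pipeline is exactly idempotent — a single pass is not, because
removing an extreme shrinks the cell's scale estimate.

## Validation suite

*Parameter recovery*: per iteration, draw fresh subject coefficients from
the generating distributions, simulate every designed trial, refit the
identical spec, and pair generating group means with recovered group-level
posterior means. Metrics per family: Pearson r pooled across nodes and
iterations; bias and RMSE computed per node then averaged (|bias| in
magnitude); quality tiers excellent (r > .90, |bias| < .05, RMSE < .10),
good (r > .80, |bias| < .10, RMSE < .20), acceptable (r > .70, |bias| <
.15, RMSE < .30), else flagged — all three conditions required per tier.

*Null-model trade-off*: generate with thresholds constant at the grand
mean (a = 2.54; subjects still vary in overall caution) while drift and
non-decision time keep their condition structure; fit with thresholds
free; the fitted lucid-REM threshold coefficient is then pure parameter
trade-off. The report summarizes the spurious distribution (mean, SD, max,
95th percentile) and compares an injected real-scale effect against it.

*Posterior predictive checks*: simulate datasets from thinned posterior
subject-level draws under the observed trial structure and compare
accuracy and RT summaries (median, quartiles, tail mass) with the data.

*Model comparison*: fit the four nested variants and tabulate DIC, pD and
ΔDIC versus the best; ΔDIC > 10 is flagged as strong evidence. The
model-recovery validation runs at two-session trial volume (27 subjects ×
~100 trials): at single-session volume the FULL generator's data still
rank FULL first, but the margin over the main-effects model (interaction
deviance gain ≈ 40 against a complexity cost ≈ 35) stays below the
strong-evidence bar, so the protocol uses the volume at which the
comparison has discriminating power.

*Within-subject coupling*: Pearson correlation between per-subject changes
(state B − state A) in two parameters, from posterior-mean subject
coefficients averaged over stimuli; the p-value uses the t transform of r.

## Problem sizes and what they show

The recovery and null-model protocols used by `scripts/acceptance.py` run
5 iterations of the 27-subject design with 2 chains × 3,000 sweeps
(burn-in 500); the test suite runs the same protocols with the same chain
lengths and 5 iterations for recovery, lighter fits (2 × 1,500–2,000) for
the null-model, DIC and mixed-model checks. At these sizes drift-rate and
non-decision-time pooled recovery r comes out near 0.95–0.97 with
stimulus-contrast RMSE ≈ 0.03–0.07 for non-decision time.

A documented limitation: stimulus-contrast RMSE for *drift* pools the
word × REM and word × lucid interaction nodes, whose posterior spread is
0.15–0.30 because those cells contain only ~60–100 trials in total under
the assumed stage weights. Same-data refits across MCMC seeds move these
estimates by < 0.01 and chains three times longer do not move them, so the
~0.1–0.15 RMSE observed for drift contrasts is an information floor of the
assumed trial structure, not a sampler deficiency. Tightening it would
require more sleep-stage trials (or a sleep-stage-heavier allocation) than
the emulated design provides.

## Numerical choices

* WFPT series tolerance 1e-6; density returns 0 for non-positive decision
  times; log-density uses a −1e300 sentinel that survives arithmetic.
* Euler dt 1e-4 (oracle-grade); 5e-4 is adequate for bulk demonstration
  runs; horizon 30 s with truncation flags.
* HDI: shortest contiguous interval containing ⌈mass·n⌉ sorted samples;
  requires ≥ 100 samples.
* R-hat: rank-normalized split R-hat (via arviz); zero-variance draws
  return NaN as an undefined-value sentinel.
* Seeds: every stochastic entry point takes an explicit seed; iteration
  seeds are derived by fixed affine maps, and kernel RNG state is seeded
  from the caller's generator, so the whole suite is reproducible
  single-threaded.
* Exclusion bookkeeping tallies each removed trial under the first rule
  that catches it, in the documented order.
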