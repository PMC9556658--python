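# Methods

This note documents the models implemented in `choicehist`, the synthetic
cohort that exercises them, the numerical choices behind the diffusion-model
likelihood, and what the validation studies do and do not establish.

## Task and data model

The package analyzes a two-interval motion-coherence discrimination task:
on each trial a reference stimulus (70% coherence) is followed by a test
stimulus whose coherence deviates by a small, individually titrated amount,
and the observer reports "stronger" or "weaker" with a fixed hand mapping
under a 3 s response deadline. The canonical in-memory objects are two tidy
DataFrames aligned row-for-row:

* a **trial table** (`subject_id, session, block, trial, stimulus,
  coherence_delta, choice, action, rt, outcome, choice_hand_map`), with
  stimulus and choice signed (−1 weaker / +1 stronger); and
* a **neural signal table** of trialwise scalar band-power modulation values
  (% change from a pre-trial baseline) per region × band × window:
  parietal IPS2/3 gamma (reference and test windows), parietal IPS0/1 alpha
  (test), a spatially unspecific "global" alpha component, and motor beta
  lateralization (reference and test).

## Synthetic cohort

The generator emulates the study conditions end to end so every analysis is
testable without any data download: 60 observers × 2 sessions × 600 trials
in blocks of 100 (all configurable).

**Stimulus sequences.** Counterbalancing is implemented as a shuffled
balanced transition list per block: of the `n−1` transitions, repeats and
switches differ in count by at most one, with the odd transition a switch so
both categories always occur. This is the minimal scheme satisfying the
design property; how counterbalancing interacted with block boundaries in
the original protocol is unknowable from the outside, so blocks are
counterbalanced independently.

**Agents.** Each observer is a drift-diffusion agent (see below) whose drift
receives, besides the stimulus term, an additive bias
`Σ_k w_k · choice_{t−k}` over the past K = 7 choices (geometric kernel,
decay 0.6), and whose starting point is nudged on the logit scale by the
previous action. Repeaters draw the kernel amplitude from N(0.28, 0.12)
truncated positive, alternators from its mirror; the action→starting-point
weight is drawn from N(−0.08, 0.05) for everyone (a group-level alternation
push). These settings yield repetition probabilities spanning roughly
0.35–0.72 with ~0.69 accuracy and ~0.85 s mean RT, comparable to the
behavioral ranges the analyses are meant to handle. Agent parameters are
fixed across sessions, so individual P(repeat) is stable across sessions by
construction. A 2% uniform lapse (random choice, uniform RT) exercises the
lapse terms of the psychometric models. Trials that would miss the deadline
are regenerated; history resets at block boundaries.

**Neural codes.** Signals are generated *downstream* of behavior: gamma
carries the previous choice (in repeaters only, sustained across windows,
plus the current stimulus during test); alpha carries an error-conditional
previous-choice code plus a loading on a global error-related suppression
shared with the `alpha_global` column; beta carries the previous action in
the raw right-hand-referenced convention, so its sign flips with the
observer's "stronger" hand. Noise SD is 15 (power-modulation units) with
subject intercept SD 3 and effect sizes 0.6–1.0, chosen so that
single-subject effects are weak (|t| ≈ 2 at 1,200 trials) while group-level
mixed-model effects are decisive at n = 60 — the regime the analyses target.
Because the signals are generated from the previous choice without feeding
back into the next one, the cohort has a-path mediation structure only;
non-zero indirect effects are exercised by a dedicated generator
(`simulate_mediation_data`) that draws the mediator system directly. What
passing tests show is therefore that the *pipeline* recovers whatever
structure is present — not that real cortical data has this structure.

## Psychometrics

Accuracy is modeled as a cumulative Weibull
`ψ(c) = δ + (1−δ−γ)(1−exp(−(c/α)^β))` with the guess rate δ pinned at 0.5,
fit by maximum likelihood (Nelder–Mead, 5 starts; lapse bounded in
[0, 0.1] to avoid the threshold/lapse trade-off at a few hundred trials per
level). The 70%-correct threshold is the fitted curve's inverse at 0.70.
The 2-up-1-down staircase steps 0.1% coherence up on errors and down after
two consecutive correct responses; its accuracy fixed point is √0.5 ≈ 70.7%
correct. The threshold estimator is the mean of the last 6 reversals —
standard adaptive-psychophysics practice; the original estimator is not
recoverable from the text.

Observers are labeled repeaters (pooled P(repeat) > 0.5) or alternators
(< 0.5) across both sessions; exactly 0.5 is excluded. A per-subject
two-sided t-test of block-wise P(repeat) against 0.5 flags individually
significant biases (undefined with one block or zero variance, in which case
the label is still assigned and the test flagged).

## History kernels

The history model is a lapse-mixed logistic psychometric:
`P(r_t = 1) = γ + (1−γ−λ) g(δ' + δ_hist + α s̃_t)` with
`δ_hist = Σ_k ω_k h_kt` over K = 7 lags of previous stimuli and choices.
Each lag set is projected onto B = 3 exponentially decaying basis functions
(unit-sum rows, decay constants τ = 1, 2.5, 6.25 lags — a geometric ladder
spanning one to roughly all seven lags; exposed in the API). ω is recovered
exactly as `basisᵀ · coefficients`. Estimation is penalized ML (tiny ridge
1e-4 on basis coefficients) by L-BFGS with a simplex polish, started from
the fitted no-history model so the nested-model likelihood inequality holds
by construction; an EM formulation would maximize the same likelihood and is
not separately implemented. Lapses are transformed through scaled logits and
bounded at 0.1: with a single stimulus intensity per observer (the
threshold-tested regime) large lapses and extreme sensitivity are
observationally equivalent, and the bound removes that degeneracy. Kernel
standard errors come from a finite-difference Hessian at the optimum. The
signed intensity is the coherence delta, z-scored per subject by default.

## Streak analysis

A repeat-ending sequence of length L at measurement trial t+1 is L identical
choices ending at t; an alternate-ending one is L identical choices followed
by a deviating choice at t. Events are nested across lengths (a length-3
streak also furnishes length-1 and length-2 events) and never cross block or
session boundaries; for a fixed length ≥ 2 each measurement trial belongs to
at most one (length, end) cell, and the length-1 repeat cell — every trial —
makes the length-1 value reflect each observer's repetition probability.

The repeating bias per (subject, length, end) cell is the SDT criterion
`c = −0.5(Φ⁻¹(H) + Φ⁻¹(F))` on the measurement trials, computed separately
for sequences ending in a "stronger" vs "weaker" choice, sign-referenced so
positive always points toward the final choice (negate after "stronger"
finals, keep after "weaker"), then averaged across the two identities
weighted by event count. Extreme rates are shrunk by half a pseudo-count
(1/(2N)). Within-group tests use pingouin's two-way repeated-measures ANOVA
(length × end); the subgroup comparison is a split-plot ANOVA (two within
factors, one between) implemented by classical sums-of-squares partitioning,
with within-effects tested against their effect-by-subject(group) strata.
Its type-I calibration is itself verified by simulation in the test suite.

## Neural encoding

Each signal is modeled as `n ~ 1 + s + c₋₁ + (1|subject)` (REML linear mixed
model, statsmodels), with the subgroup variant `n ~ 1 + s + g*c₋₁ +
(1|subject)`, all predictors coded −1/+1. Wald 95% intervals are reported; a
singular random-intercept fit falls back to subject-clustered robust OLS and
is flagged. P-values across the tested signal family are adjusted by
Benjamini–Hochberg FDR; the package routine is statsmodels' step-up,
cross-checked in tests against a brute-force implementation of the step-up
definition. Values with |power modulation| > 500 are dropped before
modeling. Two preprocessing utilities mirror the signal definitions: the
global error-related alpha component is removed from parietal alpha by
per-subject linear projection (residual orthogonal to the global regressor
within subject; zero-variance regressors pass through with a warning), and
motor lateralization is sign-flipped per subject so it is always referenced
to the "stronger"-reporting hand.

## Mediation

Per subject, the three candidate mediators are regressed linearly on the
previous choice (beta and alpha also on the current stimulus; gamma on the
previous choice alone), and the current choice is regressed logistically on
all three mediators, the previous choice, and the stimulus. The indirect
effect through mediator k is `a_k · b_k`, the direct effect `c'`, and the
total `Σ a_k b_k + c'` — identities that hold exactly by construction.
Standardization: linear paths by `sd(x)/sd(y)`; logistic paths on the
latent-response scale, dividing by `sqrt(var(Xβ) + π²/3)`. The original
WLSMV-style SEM estimator is not reimplemented: this system is recursive
with independent equation errors, so full-information ML factorizes exactly
into the two stages fit here; a linear-probability cross-check (with
first-order latent rescaling) agrees in sign and coarse magnitude in the
tests. On separation in the logistic stage the fit falls back to a ridge
penalty and is flagged. Group inference is by one-sample t-tests of the
standardized per-subject coefficients against zero and Welch tests between
subgroups, as plain as that.

## Drift-diffusion model

The accumulator has unit noise on [0, a] with the upper bound coding
"stronger" (stimulus coding); the bound separation can be static, linear
(`max(a − slope·t, floor)`), or Weibull, `b(t) = a·exp(−t^shape/scale)`,
collapsing symmetrically toward `a/2`. The relative starting point z refers
to the initial separation. Trialwise maps: `v_t = v0 + v_s·s + Σ v_j n_j`;
`z_t = logistic(logit(z0) + Σ z_j n_j)` (the logistic link keeps z in (0,1);
the original link is not stated anywhere, so this is a design choice);
optional bound modulation `a_t = a·exp(Σ w_j n_j)` (log link keeps a > 0).

**Simulator.** Euler–Maruyama (default 1 ms) with a Brownian-bridge
intra-step crossing correction, which removes the O(√dt) first-passage bias;
trials not absorbed by a 10 s horizon are resampled, then forced and
flagged.

**Likelihood.** Per-trial densities come from a Crank–Nicolson solve of the
forward (Fokker–Planck) equation in boundary-fitted coordinates: mapping the
shrinking domain onto [0, 1] turns the moving-boundary problem into fixed
Dirichlet conditions with an extra advection term `(ξ−½)·s'(t)/s(t)`. The
first ~50 ms are warm-started from the exact constant-bound image-method
solution (the bound moves < 0.5% there for every supported form), which
eliminates the delta-initial-condition transient; first-passage densities
are the boundary fluxes with second-order one-sided derivatives. The
separation is floored at 5% of its initial value so the mapped operator
stays conditioned; residual mass there drains within milliseconds.
Validation grid: dt = 1 ms, ≥ 240 space nodes (sup-norm error vs the
constant-bound series < 1e-3); fitting grid: dt = 8 ms, 80 nodes (likelihood
differences vs the fine grid are < 1 unit at n = 4000, far below the AIC
scale of interest). Because the starting point enters only the initial
condition, one tridiagonal sweep per drift node serves all starting-point
nodes; the likelihood tabulates densities over a (drift × start[× bound
scale]) grid — exact nodes when a parameter takes ≤ 8 distinct values (the
common case: ±stimulus drift), otherwise 9 (7 for bound scale) linear nodes
— and interpolates multilinearly. The solve extends to the slowest observed
response (capped at 10 s): truncating at the deadline silently discards
process tail mass and measurably biases bound-shape comparisons toward
collapse.

Five percent of trials are treated as contaminants, uniform over choices and
response times within (0, deadline] and zero beyond, so the mixture remains
a proper density. Data simulated for recovery studies include the same
contaminant fraction: fitting the mixture to contaminant-free data is
misspecified and genuinely rewards a spurious late bound collapse (verified
by quadrature during development).

**Fitting.** Staged Nelder–Mead MLE: base accumulation parameters first
(weights pinned at zero), then regressor weights conditional on the base
parameters, with an optional joint polish. Parameters are transformed to an
unconstrained scale (log bound, logit z and t0, bounded-logit collapse
shape in [0.5, 8]). Initialization is moment-based (accuracy → stimulus
drift; RT quantiles → t0 and collapse scale). Bound-model comparison is by
AIC across the three geometries on identical data. A random-walk Metropolis
sampler (default 2,000 samples, first tenth discarded as burn-in, proposal
scale adapted during burn-in toward 25% acceptance) provides posterior
summaries over the same likelihood when `method="mcmc"`; fits are per
subject with group-level t-tests downstream — no hierarchical shrinkage
across subjects is implemented.

## Problem sizes of the validation studies

The packaged studies run on one CPU core in roughly 12 minutes total:
solver vs series plus a 100,000-trial simulator GOF; regression-weight
recovery with 20 replicates × 5,000 trials (v_γ = +0.15, z_β = −0.10);
bound-geometry recovery with 20 replicates × 5,000 trials; history-kernel
recovery with 40 replicates × 10,000 trials plus 8 null fits; mediation
type-I calibration over 500 cohorts of 20 subjects × 300 trials and a
recovery cohort of 30 × 1,200; streak-interaction power over 20 repeater
cohorts of 60 subjects × 600 trials; a 4,000-trial staircase; and 1,000
random FDR vectors.

## Known limitations

* Per-subject DDM fits with group tests approximate, but are not, a
  hierarchical group posterior; shrinkage would change small-sample
  individual estimates.
* The staged MLE conditions the regressor weights on base parameters fit
  without them; the optional joint polish removes the (small) residual bias
  at extra cost.
* The cohort generator's neural signals do not causally drive its behavior,
  so cohort-level indirect mediation effects are near zero by construction
  (the a-path structure still separates subgroups); causal mediation is
  exercised only by the dedicated generator.
* Single-intensity designs leave sensitivity and lapse rates of the history
  model only weakly identified; the lapse bound is a pragmatic, not a
  principled, resolution.
* The split-plot streak ANOVA assumes sphericity; no Greenhouse–Geisser
  correction is applied to the between-group table (the within-group
  pingouin table reports one).
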