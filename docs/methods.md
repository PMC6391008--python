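# Methods

This note documents the models implemented in `twostage`, the choices made
where the design was genuinely open, and what the simulation studies do and
do not show.

## The task

Each trial of the two-stage task has two decisions. A first-stage choice
between two options leads probabilistically to one of two second-stage
states: each option has a fixed 70% ("common") destination and a 30%
("rare") one, mirrored between the options (we fix the labelling so option
1 commonly leads to state 2 and option 2 to state 3; the task is symmetric
under relabelling). Each second-stage state offers two bandits paying a
binary reward. The four reward probabilities follow independent Gaussian
random walks (step SD 0.025) reflected at [0.25, 0.75] — the canonical
design — so values must be tracked continuously. Sessions run in
`n_blocks` (default 2) equal blocks separated by a break; the canonical
session lengths are 121 (short) and 201 (long) trials. Subjects respond
within 2 s in the real task; simulation does **not** impose that deadline
by default, keeping the generative process identical to the fitted
likelihood (which has no censoring term). An optional `deadline_s`
resamples timed-out stage decisions for task-realistic data.

## Hybrid learner (value recursion)

Model-free values are learned by SARSA prediction errors, all Q initialised
to zero at session start:

    Q_mf(a2) <- Q_mf(a2) + alpha2 * (r - Q_mf(a2))
    Q_mf(a1) <- Q_mf(a1) + alpha1 * (Q_mf(a2) - Q_mf(a1))
                         + alpha1 * lambda * (r - Q_mf(a2))

where the second line uses the stage-2 value *before* its own update (both
prediction errors are computed from pre-update values, then committed — the
standard SARSA(lambda) reading; asserted by test). `lambda` is the
eligibility trace carrying the stage-2 prediction error back to stage 1.
Model-based stage-1 values look forward through the (known, not learned)
transition probabilities:

    Q_mb(a) = P(s_a | a) * max Q_mf(s_a) + P(s_o | a) * max Q_mf(s_o)

and net stage-1 values blend the systems and add a perseveration bonus `p`
for the previous trial's action (none on a block's first trial):

    Q_net = (1 - w) * Q_mf + w * Q_mb + p * Stay

`w` in [0, 1] is the model-based weight: 0 pure model-free, 1 pure
model-based. Unchosen and unvisited values do not decay. The choice-only
likelihood is a softmax over Q_net at stage 1 (inverse temperature beta1)
and over the visited state's Q_mf at stage 2 (beta2). The 5-parameter
variant ties alpha1=alpha2, beta1=beta2; the 7-parameter variant frees
them.

## Diffusion likelihood (choice + RT)

The joint model replaces the softmax with a Wiener diffusion at each stage:
evidence with unit noise SD drifts between absorbing boundaries separated
by `a`, starting midway (no response bias), with trial drift

    delta = b * (Q(chosen) - Q(unchosen))

and the chosen option at the upper boundary (equivalently a drift-sign
convention). RT is first-passage time plus a non-decision time `tau`.
Stage 1 uses Q_net, stage 2 the visited state's Q_mf; the 8-parameter
variant shares (b, a, tau) across stages, the 11-parameter variant frees
them. There are no inter-trial variability parameters.

The first-passage density uses the two classical absolutely convergent
series (small-time Gaussian-image expansion; large-time eigenfunction
expansion), switching per evaluation to whichever needs fewer terms at
truncation tolerance 1e-8 (normalised units). Observed rt <= tau, or a
density below 1e-10, contributes log(1e-10) instead of -inf so optimisers
remain stable; both constants are exposed as arguments.

**Sampling.** With a midway start the exit side and the exit time are
independent: both conditional time densities are proportional to
exp(-delta^2 t / 2) g(t; a). The side is therefore drawn from the exact
logistic absorption probability 1/(1+exp(-a*delta)) and the time by
inverting a precomputed conditional quantile table in (kappa = a*|delta|,
u) — normalised time depends on kappa only — with an asymptotically exact
exponential tail (rate (kappa^2 + pi^2)/2) beyond the last tabulated
quantile. Table resolution (321 kappa points to 40, 1024 quantiles,
4096-point time grid) keeps the KS distance to the analytic law at or
below Monte-Carlo noise for n = 2e5. Kappa beyond 40 is clamped (the
canonical parameter ranges top out near 30). A bridge-corrected
Euler–Maruyama sampler (crossing probabilities between grid points,
midpoint time correction) is retained as an independent oracle.

## Model-agnostic scores

* `MB-I(choice)`: the transition x reward interaction on the probability
  of repeating the previous first-stage choice, computed from the four
  conditional stay probabilities. Zero for a pure reward-driven
  (model-free) learner, positive for a model-based one.
* `MB-II(RT)`: mean second-stage RT after rare minus after common
  transitions, in seconds. Model-based first-stage choices steer common
  transitions toward the state with the best (and, mechanistically, most
  discriminable) bandit pair, so model-based agents are relatively faster
  after common transitions.

Stay pairs spanning a block break or a dropped trial are excluded (the
conservative reading; only first-trial omission is prescribed). Both
scores also come in hierarchical variants: per-subject conditional slopes
from cohort-level mixed models (logistic for stay with full-factorial
fixed effects and independent per-subject random effects, fit by
variational Bayes; linear for RT2 with random intercept and slope, REML).
The trial-level regressors use +1/-1 coding (common/rewarded positive);
the hierarchical MB-II is reported as rare-minus-common seconds so both
conventions read "positive = more model-based". On non-convergence the
individual scores are substituted with a warning.

eta^2 effect sizes are classical (not partial) SS_effect/SS_total computed
over subject-level condition-cell means.

## Fitting

Individual fits maximise the likelihood with scipy differential evolution
over box bounds (Sobol initialisation, default popsize multiplier 15, 150
generations) plus an L-BFGS-B polish; deterministic given the seed. A
genetic-algorithm optimiser would be interchangeable here — the optimiser
is a means, not part of the model. Default bounds cover the documented
parameter ranges; recovery studies use the sampling ranges as bounds.

Hierarchical fits run expectation-maximisation with per-parameter Gaussian
random effects in unconstrained space (logit for [0,1] parameters, log for
positive ones, identity for perseveration): the E-step finds each
subject's MAP (L-BFGS-B) and a Laplace covariance from a central-difference
Hessian (singular Hessians fall back to the prior variance, logged); the
M-step applies the standard moment update with a 1e-6 variance floor;
convergence is a relative change in total approximate evidence below 1e-4
(cap 200 iterations). The integrated BIC is
-2 * sum of Laplace log marginal likelihoods + n_hyper * log(N_obs), with
n_hyper = 2 x (number of parameters) and one observation per recorded
response (two per trial); differences of 10+ points are treated as strong
evidence.

## Simulation studies

All studies derive every random stream from a single seed and emit tables
plus a run manifest through the CLI.

* **Parameter recovery**: agents drawn uniformly from the canonical ranges
  (alpha, lambda, w in [0,1]; beta in [1,8]; p in [0,.5]; b in [1,10]; a in
  [1,3]; tau in [.01,.5]), simulated, refit, Spearman-correlated per
  parameter. At 200 trials the model-based weight recovers at roughly
  r ~ .6 under the choice-only model and ~ .85-.9 under the joint model —
  the joint model's headline advantage.
* **Split-half reliability**: odd/even halves defined by the *outcome*
  trial's parity (the conditioning trial's coding is kept regardless of
  its parity), Pearson across subjects, Spearman-Brown step-up 2r/(1+r).
  The reliability-vs-trials curve truncates sessions to their first n
  trials over a configurable grid.
* **w sweep**: w from 0 to 1 in .1 steps, each level simulating
  experiments with the other diffusion-model parameters uniform in the
  canonical ranges. Tracked per trial (pre-update): the within-state Q
  spread (max - min) of the visited state by transition type, of the state
  holding the globally best bandit vs the other state, and whether the
  best state was reached via a common transition. The default
  full-scale sweep is 200 experiments x 5000 trials; the bundled studies
  use reduced sizes (tens of experiments x 2000 trials), which leave the
  means well inside their Monte-Carlo noise.
* **Power**: two groups of agents whose w is drawn from truncated (to
  [0,1]) Gaussians with SD .1 and means .49/.51 (small, d=.2), .475/.525
  (medium, d=.5), .46/.54 (large, d=.8), or equal means for type-I-error
  calibration; each agent's session is simulated under the 11-parameter
  diffusion model, (MB-I, MB-II) computed, and the two-group MANOVA
  tested via Wilks' lambda with Bartlett's chi-square approximation
  (df = 2) at alpha = .05. Power is the significant fraction of
  iterations.

## What the synthetic cohorts do and do not emulate

Simulated cohorts draw all parameters independently and uniformly from the
canonical ranges. Real cohorts differ in ways that matter for absolute
psychometric numbers: empirical parameter distributions are concentrated
(fitted w values cluster with SD near .1; drift scalings and thresholds
are far from uniform over their plausible ranges), responses are censored
at the 2 s deadline, and parameters are mutually correlated. Consequently
the studies here reproduce *mechanisms* and *orderings* robustly (the
joint model's recovery advantage; the value-spread asymmetry between best
and worst states; score monotonicity in w; type-I calibration and power at
small separations) while quantities dominated by between-subject nuisance
variance — power at large separations, and the relative reliability of the
RT score versus the choice score — are sensitive to the unknown empirical
parameter distribution and land below their published counterparts under
the uniform convention. The `PowerConfig`/cohort helpers accept explicit
ranges so narrower populations can be explored.

## Numerical and degenerate-input conventions

* Reflected walks fold the unbounded trajectory analytically; zero step SD
  yields constant walks.
* Ties in `max` for the best-state label resolve to the lower state index;
  equal Q values give exactly zero drift and an unbiased diffusion choice.
* Undefined scores (an empty stay cell, a missing transition type)
  propagate as NaN and are dropped pairwise with counts reported.
* Fit failures are flagged (`converged=False`), never silently raised;
  recovery and power iterations exclude and count failures.
* All public entry points are bit-reproducible given their seed; derived
  streams come from `SeedSequence` spawning and stay below 2^31.

## Problem sizes of the bundled studies

The default test-suite and reproduction runs use reduced designs chosen to
keep Monte-Carlo error comfortably inside the tolerances they are checked
against: recovery with 40 agents (published analyses used 100), power with
300-1000 iterations (vs 1000), sweeps with 10-50 experiments per w level
(vs 200) of 2000 trials (vs 5000), reliability cohorts of 300 agents.
Every study scales back up through its config object.
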