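# Methods

## The problem

A receiver meets a sequence of signallers, one at a time. Each signaller is
either desirable (type A: accepting it pays a benefit `b`) or undesirable
(type B: accepting costs `c`); rejecting pays exactly 0 and — crucially —
reveals nothing. A continuous cue `x` carries probabilistic information
about the type: in the normal–normal equal-variance model the cue is
`N(mu_A, sigma^2)` or `N(mu_B, sigma^2)` depending on type, and type A
occurs at base rate `rho`. Classical signal detection theory (SDT) assumes
the receiver knows all of this and accepts whenever the expected payoff is
positive, i.e. whenever the cue is on the profitable side of

    x* = (mu_A + mu_B)/2 + sigma^2 ln(c(1 - rho)/(b rho)) / (mu_A - mu_B).

This package treats the same problem as a *one-armed contextual bandit*: a
naive receiver must learn the cue–type relationship from the signallers it
accepts while simultaneously exploiting what it has learned. Because the
log odds of type A are affine in `x` for both the normal and the
negative-exponential (power-law) cue families, the natural belief model is
binary logistic regression of type on cue.

## Belief model

The belief is a bivariate Gaussian (Laplace / quadratic) approximation to
the posterior over the logistic intercept and slope `(alpha, beta)`:

- priors `alpha, beta ~ N(0, 10^2)` (sd 10), starting values `(0, 0)`;
- the posterior mean is the MAP of the penalized Bernoulli log-likelihood
  of the accepted signallers' types on their cues, found by damped Newton
  iteration (gradient tolerance 1e-8, at most 100 iterations, backtracking
  line search with a full-step fallback once the Armijo decrease falls
  below float rounding);
- the covariance is the inverse negative Hessian at the MAP.

The belief is refitted from scratch after every acceptance rather than
updated incrementally; histories hold at most a few hundred points, so each
refit costs microseconds and the refit-from-scratch property ("end-of-
episode belief equals one fit to the full history") is exact by
construction. The normal prior makes the objective strictly convex, so
complete separation (e.g. a history containing only type A) still yields a
finite MAP and covariance.

Two derived quantities matter downstream. The *mean posterior probability*
`p_bar(x)` has two modes: the Monte-Carlo posterior mean over draws of
`(alpha, beta)` (default, 1000 draws), which respects the curvature of the
logistic under parameter uncertainty, and the deterministic *plug-in* value
`logistic(alpha_hat + beta_hat x)`. The simulation engine uses the MC mean;
the choice-fitting module uses the plug-in value (see "Yoked fitting"
below). The *profit threshold* — the cue at which the expected payoff of
acceptance crosses zero under current beliefs — is solved at the
posterior-mean parameters: `x = (ln(c/b) - alpha_hat)/beta_hat`, undefined
when the slope is exactly zero.

## Policies

Writing `v(p) = p b - (1 - p) c` for the expected payoff of acceptance:

| policy      | acceptance probability |
|-------------|------------------------|
| thompson    | `P(v(p) > 0)` under the posterior p-distribution at `x` |
| greedy      | `1` if `v(p_bar) > 0` else `0` |
| eps_greedy  | greedy with prob `1 - eps`, else `0.5` |
| softmax     | `logistic(v(p_bar)/tau)` |
| ucb         | greedy evaluated at the upper end of the `(1-gamma)` HPDI |
| midpoint    | accept all until one of each type accepted, then accept iff `x` on the desirable side of the midpoint of the two running type means |
| random      | `0.5` |
| sdt_oracle  | accept iff `x` strictly on the profitable side of `x*` |

Ties (`v = 0` exactly) reject for greedy/ucb/sdt_oracle (strict `> 0`); a
cue exactly at the midpoint, or coincident midpoint means, accept. The
HPDI is the shortest interval on sorted posterior-probability samples. The
Monte-Carlo policies reuse one posterior-sample vector per trial, and the
simulator draws the action from the emitted probability — for Thompson
sampling this is equivalent in distribution to drawing a single posterior
`p` and thresholding its payoff.

## Simulation engine

`run_episode` runs the encounter loop (sample signaller, evaluate policy,
draw action, update on acceptance only); `run_replicates` runs independent
episodes on per-replicate substreams spawned from one master seed, and
aggregates per-encounter acceptance probability by type, the distribution
of the final profit threshold, and cumulative payoff with a 95% CI.
Policies that never read the belief (random, midpoint, sdt_oracle) skip the
per-acceptance refits; the episode-final belief is fitted once at the end,
which is identical by the refit-from-scratch property.

## Synthetic volunteer experiment

The generator emulates a greyness categorization task: 50 trials per
volunteer; cue C drawn from `N(90 or 115, 25^2)` for good signallers and
`N(165 or 140, 25^2)` for bad ones (high/low discriminability), clamped to
[0, 255] and rescaled to `x = C/255`; base rate of good 0.7 or 0.3; payoffs
+1/−1. The four cells are presets T1 (low discriminability, low base rate),
T2 (low, high), T3 (high, low), T4 (high, high). Cues are real-valued by
default (an integer-RGB rounding switch exists); clamping rather than
resampling keeps one draw per trial and affects negligible mass (< 2e-4 in
the worst cell).

Each virtual volunteer follows a policy with a *trembling hand*: with
probability `eps` it deviates and accepts with its individual probability
`q_i`, so the realized per-trial acceptance probability is
`eps q_i + (1 - eps) p_policy`, and learning is yoked to the realized
decisions. Across a cohort, `logit q_i ~ N(0, sigma_q^2)` with `sigma_q`
drawn `Exp(1)` per cohort by default, mirroring the fitting prior so that
recovery studies are well-specified. Defaults for recovery work: trembling
rate 0.1, and Softmax generation at `tau = 0.37` — a temperature in the
range actually estimated for human participants in tasks of this design,
so recovery is validated on realistically noisy behaviour.

The generator evaluates policies with the *plug-in* `p_bar`. This keeps
generation coherent with the fitted likelihood (below), which is
deterministic for every candidate except Thompson/UCB: a volunteer
generated under the softmax rule then truly follows the softmax likelihood
being validated.

## Yoked fitting and model comparison

To ask which heuristic generated a choice log, each candidate policy's
acceptance probability is computed per trial *yoked* to the volunteer's
actual history: the belief (and midpoint state) is rebuilt from the
signallers that volunteer really accepted before that trial. Softmax is the
one candidate with a free policy parameter, so its table stores the
expected payoff `v` per trial and the likelihood applies
`logistic(v/tau)` inside the sampler; greedy's table likewise uses the
plug-in `p_bar` (making both tables deterministic), while Thompson and UCB
use 1000 posterior draws per trial under per-volunteer substreams of a
fixed seed. The candidate set is softmax, thompson, midpoint, sdt_oracle,
greedy, ucb and random; eps-greedy is simulation-only because its dither is
absorbed by the trembling hand.

The hierarchical likelihood of a log is Bernoulli with mixture probability
`eps q_i + (1 - eps) p_strategy`, priors `eps ~ Uniform(0, 1)`,
`logit q_i ~ N(0, sigma_q)`, `sigma_q ~ Exp(1)`, `tau ~ Exp(1)` (softmax
only), UCB's `gamma` fixed at 0.05. Posteriors are drawn with an
affine-invariant ensemble sampler (emcee; 80% differential-evolution, 20%
snooker moves) on an unconstrained parameterization (logit eps, log
sigma_q, non-centered q offsets, log tau) with exact Jacobian corrections.
Defaults: 32 walkers (at least `2 dim + 2`), 3000 steps, first half
discarded, thinned by 5 — a few hundred effective draws, adequate for PSIS
ranking; raise the step count for final inferences. Because ensemble
walkers interact, convergence is monitored by split-R-hat across four time
segments of the kept chain (threshold 1.05, surfaced as a warning and a
`converged` flag, never silent) plus the integrated autocorrelation time
for the effective sample size.

Models are compared by PSIS-LOO (Pareto-smoothed importance-sampling
leave-one-out) on the pointwise log-likelihood, reported on the deviance
scale (−2 elpd) with its SE, pairwise differences to the best model with
pointwise-difference SEs, Pareto-k diagnostics, and Akaike-style weights
`exp(-dPSIS/2)` normalized over the compared set. A brute-force check in
the test suite refits the model once per held-out trial on a 30-trial log
and confirms PSIS-LOO against exact leave-one-out within its standard
error. `recovery_study` wraps the full loop: generate a cohort, fit all
seven candidates, declare the PSIS-best identified.

## Problem sizes

The shipped tests and the acceptance script use: 100 replicates × 200
encounters for learned-threshold runs; 100 replicates × 50 encounters per
treatment for payoff orderings; 10 recovery simulations of 8 volunteers ×
50 trials fitted with the reduced sampler settings above (70 fits); and a
36-volunteer cohort for parameter recovery. These sizes reproduce the
method's behaviour with Monte-Carlo standard errors of ~0.02 on threshold
means while keeping a full run in minutes.

## What the synthetic data do and do not show

The generator reproduces the stimulus statistics, payoff structure,
feedback asymmetry and trial counts of the human task, with perfectly
specified volunteers (a single policy plus i.i.d. trembling). Real
participants bring everything the mixture absorbs only crudely — learning
of the deviation rate itself, attention drift, horizon effects, response
biases. Passing recovery tests therefore shows the *inference machinery*
is sound (the likelihoods discriminate the policies at the experiment's
sample sizes), not that human data will be equally decisive.

## Numerical notes and known limitations

- Acceptance probabilities in the mixture are floored at 1e-12 from 0/1;
  the floor only engages at degenerate parameter values since `eps > 0`
  with interior `q` keeps the mixture interior.
- Learned-threshold means carry a systematic footprint of *adaptive
  selection*: because data arrive only through acceptances governed by the
  current estimate, an underestimated threshold suppresses sampling above
  it and self-perpetuates, while an overestimate is corrected by accepting
  undesirable signallers. At the demonstration environment's conditions the
  100-replicate mean learned threshold for Thompson sampling and Softmax
  sits ~0.06–0.10 below the complete-information optimum of 0.549, whereas
  the same fit applied to data selected by the *fixed* optimal threshold is
  centred on it (mean 0.550, sd 0.23 at matched sample sizes). The
  replicated simulations quantify exactly this feedback effect.
- The exponential (power-law) family supports sampling, log odds and
  thresholds; the replicated-simulation figures in the tests exercise the
  normal family only.
- Loading externally collected choice logs is supported through the CSV
  schema (`volunteer_id, treatment, trial, C, x, is_good, accepted,
  payoff, cum_payoff`) but no external dataset ships with, or is validated
  by, this package.
- Horizon-aware policies, Gittins indices, unequal-variance (multi-
  threshold) SDT variants, and cut-off reinforcement-learning or exemplar
  comparison models are out of scope.
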