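"""The contextual-bandit encounter loop and replicated-run summaries.

One episode presents a naive receiver with a sequence of signallers. At
each encounter the receiver's policy converts its current belief (and, for
the midpoint rule, its running type means) into an acceptance probability;
the action is drawn from that probability. Acceptance reveals the
signaller's type and pays ``b`` or ``-c``; the accepted signaller joins the
history and the belief is refitted. Rejection pays 0 and teaches nothing.

Replicated runs summarize what the figures in this literature typically
show: per-encounter acceptance probability by signaller type, the
distribution of the learned profit threshold at the horizon, and mean
cumulative payoff with a 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .belief import (
    DEFAULT_PRIOR_SD,
    AcceptanceHistory,
    LogisticBelief,
    profit_threshold,
    update_belief,
)
from .environments import EnvironmentSpec, sample_signaller
from .heuristics import MidpointState, PolicySpec, accept_probability, update_midpoint

__all__ = [
    "TrialRecord",
    "SimulationResult",
    "ReplicateSummary",
    "run_episode",
    "run_replicates",
    "trials_to_frame",
]

TRIAL_COLUMNS = ("t", "x", "accept_prob", "accepted", "is_A", "payoff")

#: policies whose acceptance probability reads the logistic belief; for the
#: others the per-acceptance refit is skipped and the belief fitted once at
#: the end of the episode (identical by the refit-from-scratch property)
_BELIEF_POLICIES = frozenset(
    {"thompson", "greedy", "eps_greedy", "softmax", "ucb"}
)


@dataclass(frozen=True)
class TrialRecord:
    """One encounter. ``is_A`` is always recorded for analysis but is only
    revealed to the agent when it accepts."""

    t: int
    x: float
    accept_prob: float
    accepted: bool
    is_A: bool
    payoff: float


@dataclass
class SimulationResult:
    trials: list[TrialRecord]
    final_threshold: Optional[float]
    cumulative_payoff: float
    belief: LogisticBelief
    history: AcceptanceHistory
    midpoint_state: MidpointState


def run_episode(
    env: EnvironmentSpec,
    policy: PolicySpec,
    n_encounters: int,
    rng: np.random.Generator,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> SimulationResult:
    """Run one receiver through ``n_encounters`` sequential encounters.

    The belief is refitted from scratch after each acceptance only
    (rejections carry no information), so the end-of-episode belief equals
    a single fit to the full acceptance history.
    """
    if n_encounters < 1:
        raise ValueError("n_encounters must be >= 1")
    belief = LogisticBelief.prior(prior_sd)
    history = AcceptanceHistory()
    mid = MidpointState()
    needs_belief = policy.name in _BELIEF_POLICIES
    trials: list[TrialRecord] = []
    cum = 0.0
    for t in range(1, n_encounters + 1):
        sig = sample_signaller(env, rng)
        prob = accept_probability(
            policy, belief, mid, sig.x, env.b, env.c,
            env_for_oracle=env, rng=rng,
        )
        accepted = bool(rng.random() < prob)
        if accepted:
            payoff = env.b if sig.is_A else -env.c
            history.append(sig.x, sig.is_A)
            if needs_belief:
                belief = update_belief(history, prior_sd)
            mid = update_midpoint(mid, sig.x, sig.is_A)
        else:
            payoff = 0.0
        cum += payoff
        trials.append(TrialRecord(t=t, x=sig.x, accept_prob=float(prob),
                                  accepted=accepted, is_A=sig.is_A,
                                  payoff=payoff))
    if not needs_belief:
        belief = update_belief(history, prior_sd)
    return SimulationResult(
        trials=trials,
        final_threshold=profit_threshold(belief, env.b, env.c),
        cumulative_payoff=cum,
        belief=belief,
        history=history,
        midpoint_state=mid,
    )


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in trials], columns=TRIAL_COLUMNS)


@dataclass
class ReplicateSummary:
    """Across-replicate aggregate of a policy/environment condition."""

    n_reps: int
    n_encounters: int
    #: per-encounter mean acceptance probability given the signaller was
    #: type A (resp. B); NaN where no replicate drew that type at t.
    accept_prob_A: np.ndarray
    accept_prob_B: np.ndarray
    #: learned profit thresholds, one per replicate (NaN where undefined)
    thresholds: np.ndarray
    threshold_mean: float
    threshold_sd: float
    n_threshold_undefined: int
    cumulative_payoffs: np.ndarray
    payoff_mean: float
    payoff_sd: float
    payoff_ci95: float

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_encounters": self.n_encounters,
            "accept_prob_A": self.accept_prob_A.tolist(),
            "accept_prob_B": self.accept_prob_B.tolist(),
            "threshold_mean": self.threshold_mean,
            "threshold_sd": self.threshold_sd,
            "n_threshold_undefined": self.n_threshold_undefined,
            "thresholds": self.thresholds.tolist(),
            "payoff_mean": self.payoff_mean,
            "payoff_sd": self.payoff_sd,
            "payoff_ci95": self.payoff_ci95,
        }


def run_replicates(
    env: EnvironmentSpec,
    policy: PolicySpec,
    n_encounters: int,
    n_reps: int,
    seed: int,
    prior_sd: float = DEFAULT_PRIOR_SD,
    keep_results: bool = False,
) -> ReplicateSummary | tuple[ReplicateSummary, list[SimulationResult]]:
    """Independent replicate episodes with per-replicate RNG substreams.

    Replicate ``r`` uses the ``r``-th child of ``SeedSequence(seed)``, so
    any single replicate is reproducible in isolation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    results: list[SimulationResult] = []
    prob = np.full((n_reps, n_encounters), np.nan)
    is_A = np.zeros((n_reps, n_encounters), dtype=bool)
    thresholds = np.full(n_reps, np.nan)
    payoffs = np.zeros(n_reps)
    for r, child in enumerate(children):
        res = run_episode(env, policy, n_encounters, np.random.default_rng(child),
                          prior_sd=prior_sd)
        for j, tr in enumerate(res.trials):
            prob[r, j] = tr.accept_prob
            is_A[r, j] = tr.is_A
        if res.final_threshold is not None:
            thresholds[r] = res.final_threshold
        payoffs[r] = res.cumulative_payoff
        if keep_results:
            results.append(res)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # encounters where no replicate drew a given type are NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        acc_A = np.where(is_A, prob, np.nan)
        acc_B = np.where(~is_A, prob, np.nan)
        mean_A = np.nanmean(acc_A, axis=0)
        mean_B = np.nanmean(acc_B, axis=0)

    finite = thresholds[np.isfinite(thresholds)]
    thr_mean = float(finite.mean()) if finite.size else float("nan")
    thr_sd = float(finite.std(ddof=1)) if finite.size > 1 else float("nan")
    pay_mean = float(payoffs.mean())
    pay_sd = float(payoffs.std(ddof=1)) if n_reps > 1 else 0.0
    ci95 = 1.96 * pay_sd / np.sqrt(n_reps) if n_reps > 1 else 0.0

    summary = ReplicateSummary(
        n_reps=n_reps,
        n_encounters=n_encounters,
        accept_prob_A=mean_A,
        accept_prob_B=mean_B,
        thresholds=thresholds,
        threshold_mean=thr_mean,
        threshold_sd=thr_sd,
        n_threshold_undefined=int(n_reps - finite.size),
        cumulative_payoffs=payoffs,
        payoff_mean=pay_mean,
        payoff_sd=pay_sd,
        payoff_ci95=float(ci95),
    )
    if keep_results:
        return summary, results
    return summary
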