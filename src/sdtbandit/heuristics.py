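"""Acceptance policies: map (belief, state, cue, payoffs) to P(accept).

Each policy turns the current belief about P(type A | cue) into a
probability of pulling the uncertain arm (accept). Expected payoff of
acceptance at posterior probability p is ``v = p b - (1 - p) c``; rejection
is worth exactly 0.

thompson    P(v > 0) under the posterior p-distribution at the cue.
greedy      1 if v(p_bar) > 0 else 0 (strict; ties reject).
eps_greedy  greedy with probability 1-eps, else accept at random (0.5).
softmax     logistic(v(p_bar)/tau); tau -> 0 recovers greedy, tau -> inf random.
ucb         greedy evaluated at the upper end of the (1-gamma) HPDI of p.
midpoint    accept everything until one signaller of each type has been
            accepted, then accept iff the cue is on the desirable side of
            the midpoint of the two running sample means (tie accepts).
random      0.5 regardless of the cue.
sdt_oracle  the complete-information benchmark: accept iff v > 0 at the
            true optimal threshold (requires the environment).

The Monte-Carlo policies (thompson, greedy/softmax via the MC posterior
mean, ucb) reuse a single posterior-sample vector per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .belief import (
    DEFAULT_N_DRAWS,
    LogisticBelief,
    hpdi_upper,
    mean_p,
    posterior_p_samples,
)
from .environments import ConfigurationError, EnvironmentSpec, optimal_threshold

__all__ = [
    "PolicySpec",
    "MidpointState",
    "POLICY_NAMES",
    "POLICY_ABBREV",
    "accept_probability",
    "update_midpoint",
]

POLICY_NAMES = (
    "thompson",
    "greedy",
    "eps_greedy",
    "softmax",
    "ucb",
    "midpoint",
    "random",
    "sdt_oracle",
)

#: Abbreviations used in configs and figures.
POLICY_ABBREV = {
    "TS": "thompson",
    "GR": "greedy",
    "EGR": "eps_greedy",
    "SOFT": "softmax",
    "UCB": "ucb",
    "MID": "midpoint",
    "RDM": "random",
    "SDT": "sdt_oracle",
}


@dataclass(frozen=True)
class PolicySpec:
    """Which heuristic to run and its parameters.

    ``tau`` (softmax temperature), ``eps_dither`` (eps_greedy mixing rate)
    and ``gamma`` (UCB HPDI tail mass) are only consulted by the policies
    that need them. ``n_draws`` sets the posterior-sample count for the
    Monte-Carlo policies.
    """

    name: str
    tau: Optional[float] = None
    eps_dither: Optional[float] = None
    gamma: float = 0.05
    n_draws: int = DEFAULT_N_DRAWS

    def __post_init__(self) -> None:
        name = POLICY_ABBREV.get(self.name, self.name)
        object.__setattr__(self, "name", name)
        if name not in POLICY_NAMES:
            raise ConfigurationError(
                f"unknown policy {self.name!r}; valid names: "
                f"{', '.join(POLICY_NAMES)} (or abbreviations "
                f"{', '.join(POLICY_ABBREV)})"
            )
        if name == "softmax":
            if self.tau is None or self.tau <= 0:
                raise ConfigurationError("softmax requires tau > 0")
        if name == "eps_greedy":
            if self.eps_dither is None or not 0.0 <= self.eps_dither <= 1.0:
                raise ConfigurationError("eps_greedy requires eps_dither in [0, 1]")
        if name == "ucb" and not 0.0 < self.gamma < 1.0:
            raise ConfigurationError("ucb requires gamma in (0, 1)")


@dataclass(frozen=True)
class MidpointState:
    """Running sample means of accepted cues by revealed type."""

    sum_desirable: float = 0.0
    n_desirable: int = 0
    sum_undesirable: float = 0.0
    n_undesirable: int = 0

    @property
    def mean_x_desirable(self) -> Optional[float]:
        return self.sum_desirable / self.n_desirable if self.n_desirable else None

    @property
    def mean_x_undesirable(self) -> Optional[float]:
        return self.sum_undesirable / self.n_undesirable if self.n_undesirable else None

    @property
    def ready(self) -> bool:
        return self.n_desirable > 0 and self.n_undesirable > 0


def update_midpoint(mid: MidpointState, x: float, is_A: bool) -> MidpointState:
    """Fold one accepted signaller of revealed type into the running means."""
    if is_A:
        return replace(mid, sum_desirable=mid.sum_desirable + x,
                       n_desirable=mid.n_desirable + 1)
    return replace(mid, sum_undesirable=mid.sum_undesirable + x,
                   n_undesirable=mid.n_undesirable + 1)


def _value(p: float, b: float, c: float) -> float:
    return p * b - (1.0 - p) * c


def accept_probability(
    policy: PolicySpec,
    belief: LogisticBelief,
    mid: MidpointState,
    x: float,
    b: float,
    c: float,
    env_for_oracle: Optional[EnvironmentSpec] = None,
    rng: Optional[np.random.Generator] = None,
    p_method: str = "mc",
) -> float:
    """Probability of accepting a signaller with cue ``x`` under ``policy``.

    ``p_method`` selects how the posterior mean p_bar is computed for
    greedy/eps_greedy/softmax ("mc" or "plugin"); thompson and ucb always
    need posterior samples. The simulator draws the actual action from this
    probability, which for thompson is equivalent in distribution to
    sampling one p from the posterior and thresholding its payoff.
    """
    name = policy.name

    if name == "random":
        return 0.5

    if name == "sdt_oracle":
        if env_for_oracle is None:
            raise ConfigurationError("sdt_oracle policy requires the environment")
        thr = optimal_threshold(env_for_oracle)
        # accept iff the cue is strictly on the profitable side of the
        # threshold (v > 0); at the threshold itself v = 0 and the strict
        # rule rejects, matching greedy/ucb tie-breaking.
        if env_for_oracle.accept_below:
            return 1.0 if x < thr else 0.0
        return 1.0 if x > thr else 0.0

    if name == "midpoint":
        if not mid.ready:
            return 1.0
        m = 0.5 * (mid.mean_x_desirable + mid.mean_x_undesirable)
        if mid.mean_x_desirable == mid.mean_x_undesirable:
            return 1.0  # coincident means leave the rule undefined; accept
        if mid.mean_x_desirable < mid.mean_x_undesirable:
            return 1.0 if x <= m else 0.0
        return 1.0 if x >= m else 0.0

    needs_samples = name in ("thompson", "ucb") or p_method == "mc"
    samples = None
    if needs_samples:
        samples = posterior_p_samples(belief, x, policy.n_draws, rng)

    if name == "thompson":
        cutoff = c / (b + c)
        return float(np.mean(samples > cutoff))

    if name == "ucb":
        p_u = hpdi_upper(belief, x, policy.gamma, samples=samples)
        return 1.0 if _value(p_u, b, c) > 0.0 else 0.0

    p_bar = mean_p(belief, x, method=p_method, samples=samples)
    v = _value(p_bar, b, c)

    if name == "greedy":
        return 1.0 if v > 0.0 else 0.0

    if name == "eps_greedy":
        greedy = 1.0 if v > 0.0 else 0.0
        eps = policy.eps_dither
        return (1.0 - eps) * greedy + eps * 0.5

    if name == "softmax":
        return float(expit(v / policy.tau))

    raise ConfigurationError(f"unhandled policy {name!r}")  # pragma: no cover
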