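"""Generative signal-detection environments and their complete-information optima.

A receiver meets a sequence of signallers, each either desirable (type A,
worth ``b`` if accepted) or undesirable (type B, costing ``c`` if accepted),
at base rate ``rho`` for type A. Each signaller displays a continuous cue
``x`` drawn from a type-specific distribution: the classical normal–normal
equal-variance model (means ``mu_A``/``mu_B``, common ``sigma``) or the
power-law model, where the cue follows a negative exponential with
type-specific mean. In both families the log odds of a signaller being
type A is affine in ``x``, which is what licenses the logistic belief model
used by the learning modules.

This module holds the generative side and the closed-form, complete-
information optima: the acceptance threshold ``x*`` at which the expected
payoff of acceptance crosses zero, the per-type acceptance rates it implies,
and the per-encounter expected payoff of using it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "EnvironmentSpec",
    "Signaller",
    "ENV_PRESETS",
    "sample_signaller",
    "true_log_odds",
    "optimal_threshold",
    "accepts_at",
    "sdt_acceptance_rates",
    "expected_sdt_payoff",
]

_FAMILIES = ("normal", "exponential")


class ConfigurationError(ValueError):
    """Invalid environment or policy configuration."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """The generative world a receiver faces.

    Parameters
    ----------
    mu_A, mu_B:
        Mean cue value of desirable (A) and undesirable (B) signallers.
    rho:
        Base rate: prior probability that an encountered signaller is type A.
    b, c:
        Benefit of accepting an A, cost of accepting a B (both > 0).
    sigma:
        Common cue standard deviation (normal family only).
    family:
        ``"normal"`` (normal–normal equal variance) or ``"exponential"``
        (power-law model; ``mu_A``/``mu_B`` are the exponential means).
    truncation:
        Optional ``(lo, hi)`` interval; sampled cues outside it are clamped
        to the nearest bound.
    """

    mu_A: float
    mu_B: float
    rho: float
    b: float = 1.0
    c: float = 1.0
    sigma: float = 1.0
    family: str = "normal"
    truncation: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not (0.0 < self.rho < 1.0) and self.rho not in (0.0, 1.0):
            raise ConfigurationError(f"rho must lie in [0, 1], got {self.rho}")
        if self.b <= 0 or self.c <= 0:
            raise ConfigurationError("payoffs b and c must be positive")
        if self.family == "normal" and self.sigma <= 0:
            raise ConfigurationError("sigma must be positive for the normal family")
        if self.family == "exponential" and (self.mu_A <= 0 or self.mu_B <= 0):
            raise ConfigurationError("exponential family requires mu_A, mu_B > 0")
        if self.mu_A == self.mu_B:
            raise ConfigurationError("mu_A and mu_B must differ")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ConfigurationError("truncation interval must satisfy lo < hi")
            object.__setattr__(self, "truncation", (float(lo), float(hi)))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mu_A + self.mu_B)

    @property
    def accept_below(self) -> bool:
        """True when low cue values indicate the desirable type."""
        return self.mu_A < self.mu_B

    def rescaled(self, scale: float) -> "EnvironmentSpec":
        """The same environment with all cue-space quantities divided by ``scale``."""
        trunc = None
        if self.truncation is not None:
            trunc = (self.truncation[0] / scale, self.truncation[1] / scale)
        return EnvironmentSpec(
            mu_A=self.mu_A / scale,
            mu_B=self.mu_B / scale,
            rho=self.rho,
            b=self.b,
            c=self.c,
            sigma=self.sigma / scale,
            family=self.family,
            truncation=trunc,
        )


@dataclass(frozen=True)
class Signaller:
    is_A: bool
    x: float


#: The two-alternative demonstration environment used throughout the docs:
#: weakly discriminable types (1 s.d. either side of zero), majority
#: desirable, acceptance twice as rewarding as it is costly.
ENV_PRESETS: dict[str, EnvironmentSpec] = {
    "demo": EnvironmentSpec(mu_A=-1.0, mu_B=1.0, sigma=1.0, rho=0.6, b=2.0, c=1.0),
}


def sample_signaller(env: EnvironmentSpec, rng: np.random.Generator) -> Signaller:
    """Draw one signaller: its type at the base rate, its cue from the
    type's distribution, clamped to the truncation interval if configured."""
    is_A = bool(rng.random() < env.rho)
    mu = env.mu_A if is_A else env.mu_B
    if env.family == "normal":
        x = mu + env.sigma * rng.standard_normal()
    else:
        x = rng.exponential(mu)
    if env.truncation is not None:
        lo, hi = env.truncation
        x = min(max(x, lo), hi)
    return Signaller(is_A=is_A, x=float(x))


def true_log_odds(env: EnvironmentSpec, x):
    """Log odds that a signaller with cue ``x`` is type A.

    ``ln[rho f_A(x) / ((1-rho) f_B(x))]``, which is affine in ``x`` for both
    families — the property the logistic belief model relies on.
    """
    x = np.asarray(x, dtype=float)
    base = math.log(env.rho / (1.0 - env.rho))
    if env.family == "normal":
        s2 = env.sigma**2
        out = base + (env.mu_A - env.mu_B) * x / s2 + (env.mu_B**2 - env.mu_A**2) / (2 * s2)
    else:
        out = base + math.log(env.mu_B / env.mu_A) + x * (1.0 / env.mu_B - 1.0 / env.mu_A)
    return out if out.ndim else float(out)


def _log_odds_slope_intercept(env: EnvironmentSpec) -> tuple[float, float]:
    """(intercept, slope) of the affine true log odds."""
    lo0 = true_log_odds(env, 0.0)
    lo1 = true_log_odds(env, 1.0)
    return lo0, lo1 - lo0


def optimal_threshold(env: EnvironmentSpec) -> float:
    """Cue value ``x*`` at which the expected payoff of acceptance is zero.

    Acceptance is profitable when ``P(A|x) b - (1 - P(A|x)) c > 0``, i.e.
    when the log odds exceed ``ln(c/b)``; solving the affine log odds for
    equality gives the threshold. For the normal family this reduces to the
    closed form ``(mu_A + mu_B)/2 + sigma^2 ln(c(1-rho)/(b rho))/(mu_A - mu_B)``.
    """
    if env.family == "normal":
        return env.midpoint + env.sigma**2 * math.log(
            env.c * (1.0 - env.rho) / (env.b * env.rho)
        ) / (env.mu_A - env.mu_B)
    intercept, slope = _log_odds_slope_intercept(env)
    return (math.log(env.c / env.b) - intercept) / slope


def accepts_at(env: EnvironmentSpec, threshold: float, x: float) -> bool:
    """Whether cue ``x`` is on the accept side of ``threshold``.

    The accept side is the ``mu_A`` side; a cue exactly at the threshold
    (expected payoff exactly zero) counts as accepted.
    """
    return x <= threshold if env.accept_below else x >= threshold


def sdt_acceptance_rates(env: EnvironmentSpec, threshold: float) -> tuple[float, float]:
    """Per-type probability of a signaller falling on the accept side.

    Returns ``(p_accept_A, p_accept_B)``. Cue clamping does not change these
    masses for thresholds interior to the truncation interval.
    """
    if env.family == "normal":
        cdf_A = stats.norm.cdf(threshold, loc=env.mu_A, scale=env.sigma)
        cdf_B = stats.norm.cdf(threshold, loc=env.mu_B, scale=env.sigma)
    else:
        cdf_A = stats.expon.cdf(threshold, scale=env.mu_A)
        cdf_B = stats.expon.cdf(threshold, scale=env.mu_B)
    if env.accept_below:
        return float(cdf_A), float(cdf_B)
    return float(1.0 - cdf_A), float(1.0 - cdf_B)


def expected_sdt_payoff(env: EnvironmentSpec, threshold: Optional[float] = None) -> float:
    """Per-encounter expected payoff of a fixed acceptance threshold.

    ``rho b p_accept_A - (1-rho) c p_accept_B``; with the default
    (``threshold=None``) the optimal threshold is used, which maximizes this
    over all fixed thresholds.
    """
    if threshold is None:
        threshold = optimal_threshold(env)
    p_a, p_b = sdt_acceptance_rates(env, threshold)
    return env.rho * env.b * p_a - (1.0 - env.rho) * env.c * p_b
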