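"""Synthetic "virtual volunteer" choice logs emulating the greyness task.

The human task this module emulates: volunteers see a sequence of 50
solid-grey circles whose greyness C (identical RGB levels, 0 = black,
255 = white) is drawn from a normal distribution whose mean depends on
whether the signaller is good or bad (common s.d. 25; draws outside
[0, 255] are truncated). Accepting a good signaller pays +1, a bad one -1;
rejecting pays 0 and reveals nothing. Four treatments cross discriminability
(good/bad means 90/165 = 3 s.d. apart, or 115/140 = 1 s.d.) with the base
rate of good signallers (0.7 or 0.3). For modelling, cues are rescaled to
x = C/255 in [0, 1].

Virtual volunteers follow a heuristic policy with a trembling hand: on each
trial, with probability ``trembling_eps`` the volunteer deviates and accepts
with its individual-specific probability ``q``; otherwise it follows the
policy. The realized acceptance probability is therefore
``eps * q + (1 - eps) * p_policy``, and belief/midpoint updates follow the
realized decisions — exactly the mixture the fitting module estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .belief import DEFAULT_PRIOR_SD, AcceptanceHistory, LogisticBelief, update_belief
from .environments import EnvironmentSpec, sample_signaller
from .heuristics import MidpointState, PolicySpec, accept_probability, update_midpoint

__all__ = [
    "TreatmentSpec",
    "TREATMENTS",
    "VolunteerSpec",
    "CHOICE_LOG_COLUMNS",
    "generate_volunteer",
    "generate_cohort",
]

CUE_SCALE = 255.0

#: Stable ChoiceLog column order shared with the fitting module.
CHOICE_LOG_COLUMNS = (
    "volunteer_id", "treatment", "trial", "C", "x",
    "is_good", "accepted", "payoff", "cum_payoff",
)

#: Default deviation rate of virtual volunteers.
DEFAULT_TREMBLING_EPS = 0.1


@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the 2x2 discriminability x base-rate design."""

    name: str
    discriminability: str  # "low" | "high"
    base_rate: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.discriminability not in ("low", "high"):
            raise ValueError("discriminability must be 'low' or 'high'")
        if self.base_rate not in ("low", "high"):
            raise ValueError("base_rate must be 'low' or 'high'")

    @property
    def mu_good(self) -> float:
        return 90.0 if self.discriminability == "high" else 115.0

    @property
    def mu_bad(self) -> float:
        return 165.0 if self.discriminability == "high" else 140.0

    sigma: float = 25.0
    b: float = 1.0
    c: float = 1.0
    n_trials: int = 50

    @property
    def rho(self) -> float:
        return 0.7 if self.base_rate == "high" else 0.3

    def env_C(self) -> EnvironmentSpec:
        """The generative environment on the raw greyness scale."""
        return EnvironmentSpec(
            mu_A=self.mu_good, mu_B=self.mu_bad, sigma=self.sigma,
            rho=self.rho, b=self.b, c=self.c, truncation=(0.0, CUE_SCALE),
        )

    def env_x(self) -> EnvironmentSpec:
        """The same environment on the rescaled x = C/255 scale the
        belief and policies operate on."""
        return self.env_C().rescaled(CUE_SCALE)


TREATMENTS: dict[str, TreatmentSpec] = {
    "T1": TreatmentSpec("T1", "low", "low"),
    "T2": TreatmentSpec("T2", "low", "high"),
    "T3": TreatmentSpec("T3", "high", "low"),
    "T4": TreatmentSpec("T4", "high", "high"),
}


@dataclass(frozen=True)
class VolunteerSpec:
    volunteer_id: str
    policy: PolicySpec
    trembling_eps: float
    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.trembling_eps <= 1.0:
            raise ValueError("trembling_eps must lie in [0, 1]")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")


def generate_volunteer(
    vspec: VolunteerSpec,
    treatment: TreatmentSpec,
    rng: np.random.Generator,
    prior_sd: float = DEFAULT_PRIOR_SD,
    integer_cues: bool = False,
) -> pd.DataFrame:
    """Simulate one virtual volunteer through the treatment's 50 trials.

    Cues are generated as real-valued greyness C (set ``integer_cues`` to
    round them to RGB levels); beliefs and policies see x = C/255. The
    realized acceptance probability mixes the policy with the volunteer's
    trembling hand, and learning is yoked to what was actually accepted.
    """
    env_C = treatment.env_C()
    env_x = treatment.env_x()
    belief = LogisticBelief.prior(prior_sd)
    history = AcceptanceHistory()
    mid = MidpointState()
    rows = []
    cum = 0.0
    for t in range(1, treatment.n_trials + 1):
        sig = sample_signaller(env_C, rng)
        C = float(np.round(sig.x)) if integer_cues else sig.x
        x = C / CUE_SCALE
        # plug-in evaluation keeps generation coherent with the choice-model
        # likelihood the fitting module evaluates (same p_Strategy per trial)
        p_policy = accept_probability(
            vspec.policy, belief, mid, x, treatment.b, treatment.c,
            env_for_oracle=env_x, rng=rng, p_method="plugin",
        )
        p_real = vspec.trembling_eps * vspec.q + (1.0 - vspec.trembling_eps) * p_policy
        accepted = bool(rng.random() < p_real)
        if accepted:
            payoff = treatment.b if sig.is_A else -treatment.c
            history.append(x, sig.is_A)
            belief = update_belief(history, prior_sd)
            mid = update_midpoint(mid, x, sig.is_A)
        else:
            payoff = 0.0
        cum += payoff
        rows.append((vspec.volunteer_id, treatment.name, t, C, x,
                     sig.is_A, accepted, payoff, cum))
    return pd.DataFrame(rows, columns=list(CHOICE_LOG_COLUMNS))


def generate_cohort(
    policy: PolicySpec,
    treatment: TreatmentSpec,
    n_volunteers: int,
    trembling_eps: float = DEFAULT_TREMBLING_EPS,
    sigma_q: Optional[float] = None,
    seed: int = 0,
    prior_sd: float = DEFAULT_PRIOR_SD,
    integer_cues: bool = False,
) -> pd.DataFrame:
    """Independent virtual volunteers sharing a policy and trembling rate.

    Individual deviation probabilities are heterogeneous,
    ``q_i = logistic(z_i)`` with ``z_i ~ N(0, sigma_q^2)``; by default
    ``sigma_q`` is itself drawn Exp(1) per cohort, mirroring the fitting
    module's hierarchical prior so recovery studies are well-specified.
    """
    if n_volunteers < 1:
        raise ValueError("n_volunteers must be >= 1")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    if sigma_q is None:
        sigma_q = float(master.exponential(1.0))
    q = expit(sigma_q * master.standard_normal(n_volunteers))
    frames = []
    for i, child in enumerate(ss.spawn(n_volunteers)):
        vspec = VolunteerSpec(
            volunteer_id=f"v{i + 1:03d}", policy=policy,
            trembling_eps=trembling_eps, q=float(q[i]),
        )
        frames.append(
            generate_volunteer(vspec, treatment, np.random.default_rng(child),
                               prior_sd=prior_sd, integer_cues=integer_cues)
        )
    return pd.concat(frames, ignore_index=True)
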