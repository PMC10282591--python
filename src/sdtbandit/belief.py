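"""Sequential Bayesian logistic belief about P(type A | cue).

The receiver assumes the log odds of a signaller being desirable is affine
in the cue, ``logit P(A|x) = alpha + beta x``, and maintains a quadratic
(Laplace) approximation to the posterior over ``(alpha, beta)`` given the
signallers it has accepted so far: the posterior mean is the MAP of the
penalized Bernoulli log-likelihood under independent N(0, prior_sd^2)
priors, and the covariance is the inverse negative Hessian at the MAP.
Rejected signallers carry no information and never enter the history.

The belief is refitted from scratch after every acceptance (histories stay
small, so the repeated damped-Newton fits are cheap), mirroring repeated
quadratic-approximation fits rather than an incremental filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "LogisticBelief",
    "AcceptanceHistory",
    "BeliefFitError",
    "update_belief",
    "posterior_p_samples",
    "mean_p",
    "hpdi",
    "hpdi_upper",
    "profit_threshold",
]

DEFAULT_PRIOR_SD = 10.0
DEFAULT_N_DRAWS = 1000

_NEWTON_MAX_ITER = 100
_NEWTON_GTOL = 1e-8


class BeliefFitError(RuntimeError):
    """Raised when the MAP optimizer fails to converge (indicates a bug:
    the normal prior guarantees a proper, strictly convex optimum)."""


class AcceptanceHistory:
    """Ordered record of accepted signallers: (cue, was it type A).

    Rejections are never recorded — rejection yields no information.
    """

    __slots__ = ("_x", "_y")

    def __init__(self, x: Sequence[float] = (), is_A: Sequence[bool] = ()):
        self._x = [float(v) for v in x]
        self._y = [bool(v) for v in is_A]
        if len(self._x) != len(self._y):
            raise ValueError("x and is_A must have equal length")

    def append(self, x: float, is_A: bool) -> None:
        self._x.append(float(x))
        self._y.append(bool(is_A))

    def __len__(self) -> int:
        return len(self._x)

    def __iter__(self):
        return iter(zip(self._x, self._y))

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self._x, dtype=float)

    @property
    def is_A(self) -> np.ndarray:
        return np.asarray(self._y, dtype=bool)

    def copy(self) -> "AcceptanceHistory":
        return AcceptanceHistory(self._x, self._y)


@dataclass
class LogisticBelief:
    """Gaussian approximation to the posterior over (alpha, beta).

    ``mean`` is the MAP ``(alpha_hat, beta_hat)``; ``cov`` the Laplace
    covariance. With an empty history the belief equals the prior:
    mean (0, 0), covariance diag(prior_sd^2, prior_sd^2).
    """

    mean: np.ndarray
    cov: np.ndarray
    prior_sd: float = DEFAULT_PRIOR_SD
    _chol: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")

    @property
    def alpha(self) -> float:
        return float(self.mean[0])

    @property
    def beta(self) -> float:
        return float(self.mean[1])

    def chol(self) -> np.ndarray:
        if self._chol is None:
            try:
                self._chol = np.linalg.cholesky(self.cov)
            except np.linalg.LinAlgError as err:
                raise ValueError("covariance is not positive-definite") from err
        return self._chol

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "prior_sd": self.prior_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticBelief":
        return cls(mean=np.array(d["mean"]), cov=np.array(d["cov"]),
                   prior_sd=float(d.get("prior_sd", DEFAULT_PRIOR_SD)))

    @classmethod
    def prior(cls, prior_sd: float = DEFAULT_PRIOR_SD) -> "LogisticBelief":
        return cls(mean=np.zeros(2), cov=np.eye(2) * prior_sd**2, prior_sd=prior_sd)


def _neg_log_posterior(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       prior_prec: float) -> float:
    eta = X @ theta
    # log(1 + e^eta) - y*eta, computed stably
    ll = np.logaddexp(0.0, eta) - y * eta
    return float(ll.sum() + 0.5 * prior_prec * (theta @ theta))


def update_belief(history: AcceptanceHistory | Sequence[tuple[float, bool]],
                  prior_sd: float = DEFAULT_PRIOR_SD) -> LogisticBelief:
    """Laplace approximation to the posterior given the acceptance history.

    Damped Newton on the penalized log-likelihood, started at (0, 0),
    gradient tolerance 1e-8, at most 100 iterations. The objective is
    strictly convex (the normal prior regularizes complete separation), so
    non-convergence raises :class:`BeliefFitError` with diagnostics.
    """
    if not isinstance(history, AcceptanceHistory):
        pairs = list(history)
        history = AcceptanceHistory([p[0] for p in pairs], [p[1] for p in pairs])
    if len(history) == 0:
        return LogisticBelief.prior(prior_sd)

    x = history.x
    if not np.all(np.isfinite(x)):
        raise ValueError("history contains non-finite cue values")
    y = history.is_A.astype(float)
    X = np.column_stack([np.ones_like(x), x])
    prior_prec = 1.0 / prior_sd**2

    theta = np.zeros(2)
    H = np.eye(2) * prior_prec
    for _ in range(_NEWTON_MAX_ITER):
        p = expit(X @ theta)
        g = X.T @ (p - y) + prior_prec * theta
        if np.max(np.abs(g)) < _NEWTON_GTOL:
            break
        w = p * (1.0 - p)
        H = (X.T * w) @ X + prior_prec * np.eye(2)
        step = np.linalg.solve(H, g)
        if np.max(np.abs(step)) < 1e-12:
            break
        # backtracking line search keeps the iteration monotone; near the
        # optimum the Armijo decrease falls below rounding, in which case
        # the full (quadratically convergent) Newton step is taken
        f0 = _neg_log_posterior(theta, X, y, prior_prec)
        slope = float(g @ step)
        t = 1.0
        while t > 1e-6:
            cand = theta - t * step
            if _neg_log_posterior(cand, X, y, prior_prec) <= f0 - 1e-4 * t * slope:
                break
            t *= 0.5
        else:
            t = 1.0
        theta = theta - t * step
    else:
        raise BeliefFitError(
            f"Newton failed to converge in {_NEWTON_MAX_ITER} iterations "
            f"(n={len(history)}, |g|={np.max(np.abs(g)):.3e}, theta={theta})"
        )

    p = expit(X @ theta)
    w = p * (1.0 - p)
    H = (X.T * w) @ X + prior_prec * np.eye(2)
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)
    return LogisticBelief(mean=theta, cov=cov, prior_sd=prior_sd)


def posterior_p_samples(belief: LogisticBelief, x: float,
                        n_draws: int = DEFAULT_N_DRAWS,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draws of P(A|x): sample (alpha, beta) from the Gaussian belief and
    push each through the logistic at ``x``. Values are strictly in (0, 1)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    L = belief.chol()
    z = rng.standard_normal((n_draws, 2))
    theta = belief.mean + z @ L.T
    return expit(theta[:, 0] + theta[:, 1] * x)


def mean_p(belief: LogisticBelief, x: float, n_draws: int = DEFAULT_N_DRAWS,
           rng: Optional[np.random.Generator] = None, method: str = "mc",
           samples: Optional[np.ndarray] = None) -> float:
    """Mean posterior probability that a signaller with cue ``x`` is type A.

    ``method="mc"`` (default) is the Monte-Carlo posterior mean, which
    honors the curvature of the logistic (Jensen); ``method="plugin"``
    evaluates the logistic at the posterior-mean parameters — exact under a
    degenerate posterior and deterministic, used where the choice-model
    likelihood must not carry Monte-Carlo noise.
    """
    if method == "plugin":
        return float(expit(belief.alpha + belief.beta * x))
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    if samples is None:
        samples = posterior_p_samples(belief, x, n_draws, rng)
    return float(samples.mean())


def hpdi(samples: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sampled values."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def hpdi_upper(belief: LogisticBelief, x: float, gamma: float = 0.05,
               n_draws: int = DEFAULT_N_DRAWS,
               rng: Optional[np.random.Generator] = None,
               samples: Optional[np.ndarray] = None) -> float:
    """Upper endpoint of the (1 - gamma) highest-density interval of P(A|x)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if samples is None:
        samples = posterior_p_samples(belief, x, n_draws, rng)
    return hpdi(samples, 1.0 - gamma)[1]


def profit_threshold(belief: LogisticBelief, b: float, c: float) -> Optional[float]:
    """Cue value where the expected payoff of acceptance crosses zero under
    the posterior-mean parameters: solves logistic(alpha + beta x) = c/(b+c),
    i.e. x = (ln(c/b) - alpha)/beta. Returns None when beta is exactly zero
    (a flat belief has no threshold)."""
    if belief.beta == 0.0:
        return None
    return (math.log(c / b) - belief.alpha) / belief.beta
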