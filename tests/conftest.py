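import numpy as np
import pytest

import sdtbandit as sb
from sdtbandit.belief import AcceptanceHistory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_env():
    """Weakly discriminable two-type world: mu = -/+1, sigma 1, rho 0.6,
    b = 2, c = 1; optimal threshold 0.549."""
    return sb.ENV_PRESETS["demo"]


@pytest.fixture(scope="session")
def accept_all_history(demo_env):
    """2000 signallers from the demo environment, all accepted — the
    selection-free history used for belief parameter-recovery checks."""
    rng = np.random.default_rng(7)
    hist = AcceptanceHistory()
    for _ in range(2000):
        s = sb.sample_signaller(demo_env, rng)
        hist.append(s.x, s.is_A)
    return hist


@pytest.fixture(scope="session")
def recovered_belief(accept_all_history):
    return sb.update_belief(accept_all_history)


def make_short_treatment(n_trials: int) -> sb.TreatmentSpec:
    """The high/high treatment cell with a shortened session, for fast
    fitting fixtures (keeps the preset name so environments resolve)."""
    return sb.TreatmentSpec("T4", "high", "high", n_trials=n_trials)


@pytest.fixture(scope="session")
def small_cohort():
    """Two softmax virtual volunteers, 12 trials each."""
    treatment = make_short_treatment(12)
    return sb.generate_cohort(
        sb.PolicySpec("softmax", tau=0.37), treatment, 2,
        trembling_eps=0.2, sigma_q=1.0, seed=11,
    )
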