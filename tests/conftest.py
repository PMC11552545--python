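import numpy as np
import pytest

from sdokit.core import DistributionEnsemble
from sdokit.simulate import run_prediction_study, run_validation_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ensemble(rng, n, k, binary_p0=False):
    """Random simplex ensemble (optionally with one-hot pre-distributions)."""
    if binary_p0:
        P0 = np.eye(n)[:, rng.integers(0, n, size=k)]
    else:
        P0 = rng.dirichlet(np.ones(n), size=k).T
    P1 = rng.dirichlet(np.ones(n), size=k).T
    return DistributionEnsemble(P0=P0, P1=P1, n_states=n)


def rate(study, gen, test, value="significant"):
    sel = study[(study.gen == gen) & (study.test == test)]
    return float(sel[value].mean())


# ---------------------------------------------------------------------------
# session-scoped Monte-Carlo studies shared by the acceptance tests.
# Problem sizes follow the validation-study design (500 spikes, 1000
# ISI shuffles, 20 linear states, 10 ms windows); simulation counts are the
# package's desk-scale defaults.


@pytest.fixture(scope="session")
def study_full():
    """25 simulations of all eight generators, full STA+SDO batteries."""
    return run_validation_study(25, seed=20240)


@pytest.fixture(scope="session")
def study_y7():
    """100 Y7 simulations, STA + SDO batteries."""
    return run_validation_study(100, gens=("Y7",), seed=20241)


@pytest.fixture(scope="session")
def study_y1_sta():
    """100 Y1 simulations, STA battery only."""
    return run_validation_study(100, gens=("Y1",), seed=20242, run_sdo=False)


@pytest.fixture(scope="session")
def study_y5_sdo():
    """100 Y5 simulations, SDO battery only."""
    return run_validation_study(100, gens=("Y5",), seed=20243, run_sta=False)


@pytest.fixture(scope="session")
def study_y2_sta():
    """100 Y2 simulations, STA battery only."""
    return run_validation_study(100, gens=("Y2",), seed=20244, run_sdo=False)


@pytest.fixture(scope="session")
def pred_y7():
    """Prediction study on Y7 with a strong spike-triggered setpoint.

    The prediction experiment uses the +2 SD spike setpoint (the operating
    point where the spike-triggered convergence dominates post-spike state),
    distinct from the weak-setpoint significance-study default.
    """
    return run_prediction_study(
        40, ("Y7",), seed=20246, spec_overrides={"x0_spike_sd": 2.0, "k_spike": 0.2}
    )


@pytest.fixture(scope="session")
def pred_y1():
    """Prediction study on the no-effect white-noise generator."""
    return run_prediction_study(6, ("Y1",), seed=20247)


@pytest.fixture(scope="session")
def study_nulls_large():
    """No-effect generators at 2000 spikes / 2000 shuffles (12 sims each)."""
    return run_validation_study(
        12,
        n_spikes=2000,
        n_shuffles=2000,
        gens=("Y1", "Y4", "Y5", "Y8"),
        seed=20245,
        run_sta=False,
    )
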