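import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def fullsib_pedigree():
    """Two founder pairs, each with two full-sib offspring (C,D) and (G,H)."""
    from selexsim.pedigree import Pedigree, PedigreeRecord

    recs = [
        PedigreeRecord("A", None, None, 0),
        PedigreeRecord("B", None, None, 0),
        PedigreeRecord("E", None, None, 0),
        PedigreeRecord("F", None, None, 0),
        PedigreeRecord("C", "A", "B", 1),
        PedigreeRecord("D", "A", "B", 1),
        PedigreeRecord("G", "E", "F", 1),
        PedigreeRecord("H", "E", "F", 1),
    ]
    return Pedigree(recs)


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated experiment shared across estimator tests."""
    from selexsim.simulate import SimConfig, simulate_experiment

    cfg = SimConfig(n_per_line=120, seed=11, designer_restarts=2)
    return simulate_experiment(cfg)
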