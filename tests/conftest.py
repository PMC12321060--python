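import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fatiguenet.montage import default_montage
from fatiguenet.synthetic import CouplingGroup, SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def clean_config(**kwargs) -> SimulationConfig:
    """A SimulationConfig with all nuisance jitters disabled."""
    defaults = dict(
        n_subjects=1,
        duration=20.0,
        fs=250.0,
        band_power={"alpha": (1.0, 1.0)},
        coupling=(),
        noise_level=0.0,
        amp_jitter=0.0,
        band_level_jitter=0.0,
        subject_band_jitter=0.0,
        strength_jitter=0.0,
        seed=11,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def coupled_pair_config(lag: float, strength: float = 1.0, **kwargs) -> SimulationConfig:
    """Two α-coupled channels (C3, C4) at a constant phase lag, no noise."""
    return clean_config(
        coupling=(CouplingGroup(("C3", "C4"), "alpha", lag, (strength, strength)),),
        **kwargs,
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """Small cohort with the default fatigue signatures, for pipeline tests."""
    cfg = SimulationConfig(n_subjects=6, duration=10.0, fs=250.0, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240930)
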