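import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_session():
    """A deterministic 200-trial session from a mid-spread observer."""
    from metabisect import ObserverParams, ScheduleSpec, simulate_session

    obs = ObserverParams(
        phi=0.75, sigma_i1=0.15, sigma_i2=0.15, sigma_meta=0.5, subject_id="S01"
    )
    return simulate_session(
        obs, "V", 1.5, ScheduleSpec(n_trials=200, block_size=100), seed=11
    )


@pytest.fixture(scope="session")
def study_1500():
    """A small multi-subject study in the 1500 ms duration condition."""
    from metabisect import GroupParams, ScheduleSpec, sample_observers, simulate_study

    group = GroupParams(
        phi=0.75, phi_sd=0.01, sigma_i1=0.15, sigma_i2=0.15,
        sigma_meta=0.5, sigma_spread=0.2, rho=0.6,
    )
    observers = sample_observers(group, 3, seed=5)
    return simulate_study(
        observers, ("V", "A", "AV"), 1.5,
        ScheduleSpec(n_trials=60, block_size=60), seed=6,
    )


RECOVERY_GROUP = dict(
    phi=0.75, phi_sd=0.0, sigma_i1=0.15, sigma_i2=0.15,
    sigma_meta=0.5, sigma_spread=0.2, rho=0.6,
)


def make_recovery_study(n_subjects=5, n_trials=100, obs_seed=42, data_seed=42):
    """Synthetic study at the midpoint-recovery design point:
    unbiased observers (phi = 750 ms) in the 1500 ms duration condition."""
    from metabisect import GroupParams, ScheduleSpec, sample_observers, simulate_study

    group = GroupParams(**RECOVERY_GROUP)
    observers = sample_observers(group, n_subjects, seed=obs_seed)
    return simulate_study(
        observers, ("V", "A", "AV"), 1.5,
        ScheduleSpec(n_trials=n_trials, block_size=n_trials), seed=data_seed,
    )


@pytest.fixture(scope="session")
def recovery_fit():
    """Full-variant fit of the 5 x 3 x 100 recovery study (2 chains,
    1000 burn-in, 1500 retained draws). Shared across test modules."""
    from metabisect import HierarchicalBisectionModel

    data = make_recovery_study()
    model = HierarchicalBisectionModel(data, variant="full")
    return model.fit(n_chains=2, burn_in=1000, samples=3750, thin=5, seed=1)
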