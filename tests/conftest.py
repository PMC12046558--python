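import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import paddleface as pf

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

SEED = 20260923


@pytest.fixture(scope="session")
def neutral_template():
    """Noise-free all-α template with a facially neutral pocket."""
    return pf.build_template(pf.GeneratorSpec())


@pytest.fixture(scope="session")
def re_blocked_ensemble():
    """Planted Re-blocked ensemble: 2000 frames, σ = 0.15 Å."""
    spec = pf.GeneratorSpec.re_blocked(n_frames=2000, seed=SEED)
    traj, topo = pf.simulate_trajectory(spec)
    return spec, traj, topo


@pytest.fixture(scope="session")
def re_blocked_report(re_blocked_ensemble):
    _, traj, topo = re_blocked_ensemble
    series = pf.descriptor_series(traj, topo)
    return pf.facial_bias(series)


@pytest.fixture(scope="session")
def two_state_flexible_ensemble():
    """50/50 Markov mixture of Re-blocked and Si-blocked geometries."""
    spec = pf.GeneratorSpec(
        markov_states=(
            pf.MarkovState(("α", "α", "α", "α"), d_block_re=3.5, d_block_si=6.0),
            pf.MarkovState(("α", "α", "α", "α"), d_block_re=6.0, d_block_si=3.5),
        ),
        markov_transition=((0.9, 0.1), (0.1, 0.9)),
        n_frames=2000,
        seed=SEED + 1,
    )
    traj, topo = pf.simulate_trajectory(spec)
    return spec, traj, topo


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
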