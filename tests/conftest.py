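import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def tiny_pair_config(kappa, delta=math.pi / 2, seed=0, band="theta", noise_sd=0.5, fs=128.0):
    """Two-ROI, single-band, short-epoch generator config for fast tests."""
    from dmnstrat.simulate import PairCoupling, SimulationConfig

    return SimulationConfig(
        n_patients=1,
        n_controls=0,
        subgroup_sizes=(1,),
        n_rois=2,
        roi_order=("A", "B"),
        sampling_rate=fs,
        duration=24.0,
        epoch_length_s=2.0,
        n_epochs=10,
        bands=(band,),
        coupling_spec={band: (PairCoupling("A", "B", delta, kappa),)},
        coupling_variability=0.0,
        coupling_jitter=0.0,
        noise_sd=noise_sd,
        clinical_effects={},
        seed=seed,
    )


def tiny_pair_pli(kappa, delta=math.pi / 2, seed=0, band="theta", noise_sd=0.5):
    """Epoch-averaged PLI of the configured pair in one tiny simulation."""
    from dmnstrat.connectivity import BANDS, pli_matrix
    from dmnstrat.simulate import simulate_coupled_sources

    cfg = tiny_pair_config(kappa, delta=delta, seed=seed, band=band, noise_sd=noise_sd)
    cohort = simulate_coupled_sources(cfg)
    return pli_matrix(cohort.recordings[0], BANDS[band], 2.0, 10).vector[0]


@pytest.fixture(scope="session")
def planted_feature_cohort():
    """Feature-level cohort with a 19/18 two-component mixture at 4 sigma.

    The two patient components differ by 4 within-component SDs on five
    PLI features; controls sit at the midpoint.  Returned as
    (features DataFrame, truth dict, config).
    """
    from dmnstrat.simulate import SimulationConfig, simulate_feature_cohort

    sd = 0.02
    base = np.full(15, 0.15)
    m1, m2 = base.copy(), base.copy()
    m1[:5] += 2 * sd
    m2[:5] -= 2 * sd
    config = SimulationConfig(seed=11)
    features, truth = simulate_feature_cohort(config, np.vstack([m1, m2]), np.eye(15) * sd**2)
    return features, truth, config
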