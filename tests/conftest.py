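import numpy as np
import pytest

from tumorcal.data_model import ScenarioMeta, TimeCourseDataset
from tumorcal.forward_models import Grid, PhaseFieldParams, ReducedParams
from tumorcal.synthetic import SyntheticStudySpec, synth_initial_field


@pytest.fixture
def meta_mmc() -> ScenarioMeta:
    return ScenarioMeta(
        scenario_id="apo_50k", seeding_density=5e4, fbs_percent=10.0,
        treatment="MMC", duration=7.0,
    )


@pytest.fixture
def small_dataset(meta_mmc) -> TimeCourseDataset:
    times = np.arange(0.0, 8.0)
    rng = np.random.default_rng(7)
    clean = 0.0422 * np.exp(-0.09 * times)
    values = np.abs(clean[:, None] + 1e-3 * rng.standard_normal((times.size, 4)))
    return TimeCourseDataset(meta=meta_mmc, times=times, values=values)


@pytest.fixture
def reduced_params() -> ReducedParams:
    return ReducedParams(
        lambda_prol=0.5, lambda_apop=0.09, lambda_VN=0.11, K=0.14,
        phi_sigma=1.0, phi_V0=0.0422,
    )


@pytest.fixture
def grid64() -> Grid:
    return Grid(nx=64, ny=64, spacing=1160.0 / 64)


@pytest.fixture
def grid32() -> Grid:
    return Grid(nx=32, ny=32, spacing=1160.0 / 32)


@pytest.fixture
def pf_params() -> PhaseFieldParams:
    return PhaseFieldParams(M_T=200.0, E_bar_T=0.65, epsilon_T=30.0)


@pytest.fixture
def clustered_state(grid64):
    return synth_initial_field(
        grid64, n_clusters=3, cluster_radius=120.0, peak_fraction=0.9,
        interface_width=40.0, seed=7,
    )


@pytest.fixture
def study_spec() -> SyntheticStudySpec:
    return SyntheticStudySpec()
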