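import numpy as np
import pytest

from gobblewx.model import GobblingStateSpaceModel
from gobblewx.params import ModelParams
from gobblewx.simulate import SimulationConfig, WeatherControls, model_frame, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two sites, one 90-day year, known truth — shared across tests."""
    truth = ModelParams(
        beta_temperature=-0.21, beta_wind=-0.16, beta_bp=0.28,
        beta_humidity=0.09, beta_precipitation=-0.56,
        site_effect=np.array([0.20, 0.11]), year_effect=np.array([0.0]),
        sigma_year=0.05, sigma_process=0.15, rho=-0.5,
    )
    cfg = SimulationConfig(n_sites=2, n_years=1, n_days=90, units=10,
                           true_params=truth,
                           weather_controls=WeatherControls(), seed=20140301)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return model_frame(small_dataset)


@pytest.fixture(scope="session")
def fitted_small(small_frame):
    """One moderate fit with latent states retained."""
    return GobblingStateSpaceModel(
        n_chains=3, n_burnin=500, n_iterations=1500, thin=3,
        store_latent=True, random_state=11,
    ).fit(small_frame)
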