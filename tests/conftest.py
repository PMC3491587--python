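import numpy as np
import pytest

from fruitflux import (
    CampaignScenario,
    WeatherScenario,
    build_conductance_dataset,
    generate_campaign,
    generate_weather,
)


@pytest.fixture(scope="session")
def weather():
    """Default hourly synthetic weather season (noisy, seed 0)."""
    return generate_weather(WeatherScenario(seed=0), cadence_minutes=60)


@pytest.fixture(scope="session")
def quiet_weather():
    """Noise-free hourly weather, for exact-recovery oracles."""
    scn = WeatherScenario(
        seed=0, T_noise_sd=0.0, RH_noise_sd=0.0, W_noise_sd=0.0, R_noise_sd=0.0
    )
    return generate_weather(scn, cadence_minutes=60)


@pytest.fixture(scope="session")
def noiseless_campaign(quiet_weather):
    """Campaign with no fruit-level scatter and no balance noise."""
    cs = CampaignScenario(fruit_cv=0.0, weight_noise_sd=0.0, seed=0)
    weighings, truth = generate_campaign(cs, quiet_weather)
    return cs, weighings, truth


@pytest.fixture(scope="session")
def noiseless_obs(noiseless_campaign, quiet_weather):
    cs, weighings, _ = noiseless_campaign
    return build_conductance_dataset(weighings, quiet_weather, cs.full_bloom)


@pytest.fixture(scope="session")
def noisy_campaign(weather):
    cs = CampaignScenario(seed=7)
    weighings, truth = generate_campaign(cs, weather)
    return cs, weighings, truth


@pytest.fixture(scope="session")
def noisy_obs(noisy_campaign, weather):
    cs, weighings, _ = noisy_campaign
    return build_conductance_dataset(weighings, weather, cs.full_bloom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
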