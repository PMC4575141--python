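import pytest

from crescreen.plate_model import ScreenDesign
from crescreen.simulate import SimulationConfig, archetype_profiles, simulate_screen


@pytest.fixture(scope="session")
def design() -> ScreenDesign:
    return ScreenDesign()


@pytest.fixture(scope="session")
def noise_free_sim() -> SimulationConfig:
    return SimulationConfig(plate_effect_sd=0.0, well_noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_screen(design, noise_free_sim):
    """All five archetypes on one plate batch, with all noise switched off."""
    return simulate_screen(
        list(archetype_profiles().values()), design, noise_free_sim
    )


@pytest.fixture(scope="session")
def default_screen(design):
    """All five archetypes at the default noise setting, fixed seed."""
    return simulate_screen(
        list(archetype_profiles().values()), design, SimulationConfig(seed=7)
    )
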