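import numpy as np
import pytest

from isletkit.simulate import SimConfig, Simulation, preset_config


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    """Small-preset fixture shared across tests (deterministic, seed 7)."""
    return Simulation(preset_config("small", seed=7))


@pytest.fixture(scope="session")
def default_sim() -> Simulation:
    """Paper-scale fixture: 2,000 genes, 145 lncRNAs, 5 x 20 decoys."""
    return Simulation(SimConfig(seed=1))


def null_config(seed: int, **overrides) -> SimConfig:
    """A configuration with nothing planted (pure NB null)."""
    kw = dict(
        seed=seed,
        n_lnc_intronic=0,
        n_lnc_intergenic=0,
        n_decoys_per_rule=0,
        planted_beta_enriched=0,
        planted_alpha_enriched=0,
        planted_species_unique=0,
        planted_species_enriched=0,
        planted_glucose_up=0,
        planted_glucose_down=0,
        planted_glucose_lnc=0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
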