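import pytest

from pedsurv import SimulationConfig, simulate_studbook, toy_configs, \
    toy_fixtures


@pytest.fixture(scope="session")
def toy():
    """Hand-constructed pedigrees with analytically known f, kinship, G."""
    return toy_fixtures()


@pytest.fixture(scope="session")
def toy_cfgs():
    return toy_configs()


@pytest.fixture(scope="session")
def small_studbook():
    """A small multi-species studbook (mammal + clutch species)."""
    cfg = SimulationConfig(
        n_species=4, n_reptile=1, founders_per_species=12, n_years=15,
        max_breeding_females=8, seed=42)
    return simulate_studbook(cfg)


def random_pedigree(seed, n_species=2):
    """Small random studbook (<= ~200 individuals) for property tests."""
    cfg = SimulationConfig(
        n_species=n_species, n_reptile=0, founders_per_species=10,
        n_years=8, max_breeding_females=5, litter_mean=2.0,
        wild_intake_rate=0.3, seed=seed)
    return simulate_studbook(cfg)
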