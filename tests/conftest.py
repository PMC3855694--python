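import dataclasses

import pytest

from methkit import HMR_SIM, HYPERMR_SIM, PMD_SIM, hsmm_fit, simulate_methylome


@pytest.fixture(scope="session")
def hmr_sim():
    """Standard methylated-background simulation with planted HMRs."""
    config = dataclasses.replace(HMR_SIM, seed=1)
    records, truth = simulate_methylome(config)
    return config, records, truth


@pytest.fixture(scope="session")
def hypermr_sim():
    """Mosaic (plant-like) simulation with planted HyperMRs and embedded runs."""
    config = dataclasses.replace(HYPERMR_SIM, seed=2)
    records, truth = simulate_methylome(config)
    return config, records, truth


@pytest.fixture(scope="session")
def hypermr_fit(hypermr_sim):
    """Trained explicit-duration model on the standard mosaic simulation."""
    _, records, _ = hypermr_sim
    return hsmm_fit(records, l_max=200, max_iter=12)


@pytest.fixture(scope="session")
def pmd_sim():
    """Dense-CpG simulation with planted partially methylated domains."""
    config = dataclasses.replace(PMD_SIM, seed=4)
    records, truth = simulate_methylome(config)
    return config, records, truth
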