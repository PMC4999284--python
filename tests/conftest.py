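import numpy as np
import pytest

import popforce as pf


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Deterministic census/covariates generated from catalogue model 6."""
    scenario = pf.ScenarioConfig(process_sd=0.0, seed=11)
    bundle = pf.generate_bundle(scenario)
    bundle["scenario"] = scenario
    return bundle


@pytest.fixture(scope="session")
def noiseless_records(noiseless_bundle):
    return pf.growth_records(
        noiseless_bundle["population"],
        noiseless_bundle["gdp"],
        noiseless_bundle["rain"],
    )


@pytest.fixture(scope="session")
def noisy_records():
    scenario = pf.ScenarioConfig(process_sd=0.05, seed=23)
    bundle = pf.generate_bundle(scenario)
    return pf.growth_records(bundle["population"], bundle["gdp"], bundle["rain"])


@pytest.fixture(scope="session")
def ring_signal():
    """A 120-year rainfall-proxy signal for tree-ring fixtures.

    Innovation sd 0.25 gives the index a stationary sd near 0.27, the
    strong moisture signal typical of semiarid high-elevation sites.
    """
    return pf.gen_rainfall_proxy(120, mean=1.0, ar1=0.4, trend=0.0, sd=0.25,
                                 seed=5, start_year=1880)


@pytest.fixture(scope="session")
def clean_tree_set(ring_signal):
    return pf.gen_tree_ring_set(8, 120, ring_signal, noise_sd=0.0, seed=2,
                                stagger_fraction=0.0)


@pytest.fixture(scope="session")
def noisy_tree_set(ring_signal):
    return pf.gen_tree_ring_set(30, 120, ring_signal, noise_sd=0.3, seed=3)
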