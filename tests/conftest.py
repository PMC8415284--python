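"""Shared fixtures: the reference roster, a seeded synthetic world, and a
small three-species size-spectrum community that runs in well under a
second per simulated century."""

import numpy as np
import pandas as pd
import pytest

from ecocompare import derive, roster as ros, sizespectrum as ss, synthetic as syn


@pytest.fixture(scope="session")
def roster():
    return ros.build_reference_roster()


@pytest.fixture(scope="session")
def traits(roster):
    return syn.gen_traits(roster, seed=11)


@pytest.fixture(scope="session")
def diet_prefs(roster, traits):
    return syn.gen_diet_preferences(roster, seed=11, traits=traits)


@pytest.fixture(scope="session")
def small_species():
    """Three interacting species spanning two decades of asymptotic mass."""
    base = pd.DataFrame(
        {
            "group_id": ["sprat", "cod", "shark"],
            "w_inf_g": [50.0, 2000.0, 20000.0],
            "w_mat_g": [10.0, 400.0, 5000.0],
            "k_vb": [0.6, 0.25, 0.12],
            "a_lw": [0.01, 0.01, 0.008],
            "b_lw": [3.0, 3.0, 3.1],
            "M_lit": [0.9, 0.4, 0.2],
            "beta": [100.0, 80.0, 60.0],
            "sigma": [1.3, 1.5, 1.5],
        }
    )
    return ss.default_physiology(base)


@pytest.fixture(scope="session")
def small_model(small_species):
    theta = np.full((3, 3), 0.6)
    np.fill_diagonal(theta, 1.0)
    model = ss.SSModel(small_species.copy(), theta,
                       resource=ss.ResourceParams.reduced(),
                       grid=ss.GridParams(n_w=100))
    model.species["R_max"] = model.resource.kappa * model.species["w_inf_g"] ** -1.0
    return model


@pytest.fixture(scope="session")
def shipped_model():
    from ecocompare import shipped
    return shipped.load_calibrated_model()


@pytest.fixture()
def two_pool_inputs():
    """A one-prey one-predator Ecopath snapshot used across pool tests.

    Matches the hand-balanced example: prey B0=100, PB=1; predator B0=10,
    QB=5 feeding only on the prey; prey catch 10 -> EE_prey = 0.6.
    """
    inputs = pd.DataFrame(
        {
            "group": ["prey", "pred"],
            "B0": [100.0, 10.0],
            "PB": [1.0, 1.5],
            "QB": [np.nan, 5.0],
            "Y0": [10.0, 0.0],
        }
    )
    dc = pd.DataFrame({"pred": [1.0, 0.0]}, index=["prey", "pred"])
    dc.index.name = "prey"
    return inputs, dc
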