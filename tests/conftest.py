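import numpy as np
import pytest

import sedpower as sp


@pytest.fixture(scope="session")
def scenarios():
    """Solved preset scenarios, shared across the suite (solves are cached)."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = sp.make_scenario(name)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def amor(scenarios):
    return scenarios("AMOR-like")


@pytest.fixture(scope="session")
def sast(scenarios):
    return scenarios("SAST-like")


@pytest.fixture(scope="session")
def np_site(scenarios):
    return scenarios("NP-like")


@pytest.fixture
def oracle_site():
    """Constant-porosity, no-advection, reaction-free site for transport oracles."""
    return sp.SiteConfig(
        name="oracle",
        water_depth=3000.0,
        temperature=0.0,
        pH=7.79,
        sedimentation_rate=0.0,
        domain_length=0.2,
        top_concentrations={"O2": 0.2, "NO3": 0.03, "NH4": 0.0, "Mn": 0.0, "DIC": 2.3},
        organic_flux=0.0,
        porosity_surface=0.8,
        porosity_deep=0.8,
        fully_oxic=True,
    )


@pytest.fixture
def inert_params():
    return sp.KineticParameters(k1=0.0, k2=0.0, k_nit=0.0, k_mnox=0.0, k_amx=0.0)


def make_profile_set(grid, **overrides):
    """A ProfileSet of zeros except for the given species arrays."""
    n = grid.n_nodes
    solutes = {s: np.zeros(n) for s in sp.SOLUTES}
    solids = {s: np.zeros(n) for s in sp.SOLIDS}
    for k, v in overrides.items():
        target = solutes if k in solutes else solids
        target[k] = np.asarray(v, dtype=float)
    return sp.ProfileSet(grid=grid, solutes=solutes, solids=solids)
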