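import cobra
import pytest

from trichodfba import dfba, toy
from trichodfba.toy import ToyNetworkParams, make_toy_model


@pytest.fixture(scope="session")
def toy_params():
    return ToyNetworkParams()


@pytest.fixture(scope="session")
def toy_bundle(toy_params):
    """(shared model, diazotroph spec, photoautotroph spec) of the toy network."""
    return make_toy_model(toy_params)


@pytest.fixture()
def toy_model(toy_bundle):
    model, _, _ = toy_bundle
    return model.copy()


@pytest.fixture(scope="session")
def oracle(toy_params):
    """Brute-force equilibrium of the default toy network (session-cached)."""
    return toy.analytic_equilibrium(toy_params)


@pytest.fixture(scope="session")
def equilibrium_trace(toy_bundle, oracle):
    """A 400 h population run started at the oracle equilibrium fraction."""
    model, dz_spec, pa_spec = toy_bundle
    subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
    total = 4e-5
    init = dfba.PopulationState(
        t=0.0,
        X={dfba.DZ: oracle.f_dz * total, dfba.PA: (1 - oracle.f_dz) * total},
        C={"glycogen": 0.0, "nh4": 0.0},
    )
    return dfba.simulate_population(subs, init, dfba.DFBAConfig(horizon=400))


def make_inoculum(f_dz: float, total: float = 4e-5) -> dfba.PopulationState:
    return dfba.PopulationState(
        t=0.0,
        X={dfba.DZ: f_dz * total, dfba.PA: (1 - f_dz) * total},
        C={"glycogen": 0.0, "nh4": 0.0},
    )


def tiny_chain_model() -> cobra.Model:
    """A -> B -> C linear chain with exchanges for A and B only."""
    m = cobra.Model("chain")
    a = cobra.Metabolite("A", formula="C1", compartment="c")
    b = cobra.Metabolite("B", formula="C1", compartment="c")
    c = cobra.Metabolite("C", formula="C1", compartment="c")
    m.add_metabolites([a, b, c])
    r1 = cobra.Reaction("EX_A", lower_bound=-10, upper_bound=0)
    r1.add_metabolites({a: -1})
    r2 = cobra.Reaction("AB", lower_bound=0, upper_bound=1000)
    r2.add_metabolites({a: -1, b: 1})
    r3 = cobra.Reaction("BC", lower_bound=0, upper_bound=1000)
    r3.add_metabolites({b: -1, c: 1})
    r4 = cobra.Reaction("EX_B", lower_bound=0, upper_bound=1000)
    r4.add_metabolites({b: -1})
    m.add_reactions([r1, r2, r3, r4])
    return m
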