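import pytest

from biostim.model import MetabolicModel, Metabolite, Reaction
from biostim.synthetic import ToySpec, make_degrader


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Linear chain: EX_a (lb -10) -> transport -> biomass consuming 2 a_c
    per unit flux, so the optimum is 10/2 = 5 by hand LP."""
    return MetabolicModel(
        "chain",
        metabolites=[
            Metabolite("a_e", compartment="extracellular"),
            Metabolite("a_c"),
        ],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -10.0, 1000.0, is_exchange=True),
            Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            Reaction("BIO", {"a_c": -2.0}, 0.0, 1000.0, is_biomass=True),
        ],
    )


@pytest.fixture
def simple_degrader() -> MetabolicModel:
    """One-supplement degrader: glucose-like supplement with yield 0.5,
    atrazine-like target with the carbon-balanced yield 0.4."""
    return make_degrader(
        ToySpec("deg", (("glc_e", "C10H20O10", 0.5),), degrades_target=True)
    )


@pytest.fixture
def designed_community() -> list[MetabolicModel]:
    """Four species with disjoint single-supplement menus and strictly
    decreasing designed yields (0.5 > 0.45 > 0.4 > 0.35); only the first
    species degrades the target."""
    yields = (0.5, 0.45, 0.4, 0.35)
    models = []
    for i, y in enumerate(yields):
        c = int(round(y * 20))
        models.append(
            make_degrader(
                ToySpec(
                    f"sp{i}",
                    ((f"s{i}_e", f"C{c}H{2 * c}O{c}", y),),
                    degrades_target=(i == 0),
                )
            )
        )
    return models
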