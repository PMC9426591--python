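import pytest
from hypothesis import given, strategies as st

from biostim.dfba import SimConfig
from biostim.formula import element_count
from biostim.screening import (
    BASELINE_ID,
    SupplementSpec,
    build_medium,
    carbon_normalized_dose,
    nitrogen_normalized_dose,
    rank_supplements,
    read_supplements,
    screen_supplements,
    write_supplements,
)
from biostim.synthetic import community_supplement_specs, make_community


# -- dose normalization -----------------------------------------------------

@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C12H22O11", 25.0),  # maltose / trehalose: half the glucose dose
        ("C6H12O6", 50.0),    # glucose vs itself
        ("C18H36O2", 16.0),   # octadecanoate: floor(300/18)
        ("C6H9N3O2", 50.0),   # histidine
        ("C3H7NO3", 100.0),   # serine
    ],
)
def test_carbon_normalized_doses(formula, expected):
    assert carbon_normalized_dose(formula) == expected


def test_nitrogen_normalized_doses():
    assert nitrogen_normalized_dose("C3H7NO3") == 250.0   # serine vs 5-N target
    assert nitrogen_normalized_dose("C5H10N5") == 50.0    # equal nitrogen


def test_non_carbon_source_rejected():
    with pytest.raises(ValueError, match="not a C source"):
        carbon_normalized_dose("HO4P")


def test_non_nitrogen_source_rejected():
    with pytest.raises(ValueError, match="not a N source"):
        nitrogen_normalized_dose("C6H12O6")


def test_exact_mode_skips_flooring():
    assert carbon_normalized_dose("C18H36O2", exact=True) == pytest.approx(300 / 18)


@given(st.integers(1, 40), st.integers(1, 60))
def test_floor_property_dimensional_consistency(c_sup, ref_dose):
    """floored dose x supplement carbon lands in
    (ref_dose*C_ref - C_sup, ref_dose*C_ref]."""
    dose = carbon_normalized_dose(f"C{c_sup}", "C6H12O6", float(ref_dose))
    total = dose * c_sup
    assert ref_dose * 6 - c_sup < total <= ref_dose * 6


# -- build_medium -----------------------------------------------------------

def test_build_medium_composition():
    med = build_medium(target_dose=("atz_e", 50.0), supplement_dose=("maltose_e", 25.0))
    assert med.amounts == {"atz_e": 50.0, "maltose_e": 25.0}
    assert len(med.unlimited) == 11  # the mineral background ions


def test_build_medium_baseline_has_only_target():
    med = build_medium(target_dose=("atz_e", 50.0))
    assert med.amounts == {"atz_e": 50.0}


def test_build_medium_rejects_supplement_equal_to_target():
    with pytest.raises(ValueError, match="target"):
        build_medium(target_dose=("atz_e", 50.0), supplement_dose=("atz_e", 10.0))


def test_build_medium_rejects_unknown_ids_when_universe_given():
    with pytest.raises(KeyError, match="ghost_e"):
        build_medium(
            target_dose=("atz_e", 50.0),
            supplement_dose=("ghost_e", 1.0),
            known_ids={"atz_e", "glc_e"},
        )


# -- screen & rank ----------------------------------------------------------

@pytest.fixture(scope="module")
def designed_screen():
    yields = (0.5, 0.45, 0.4, 0.35)
    from biostim.synthetic import ToySpec, make_degrader

    models = [
        make_degrader(
            ToySpec(
                f"sp{i}",
                ((f"s{i}_e", f"C{int(y*20)}H{int(y*40)}O{int(y*20)}", y),),
                degrades_target=(i == 0),
            )
        )
        for i, y in enumerate(yields)
    ]
    cands = community_supplement_specs(models)
    result = screen_supplements(models, cands, mode="molar",
                                config=SimConfig(max_rounds=15))
    return models, cands, result


def test_screen_contains_baseline_and_all_candidates(designed_screen):
    _, cands, result = designed_screen
    supplements = set(result.table["supplement"])
    assert BASELINE_ID in supplements
    assert {c.id for c in cands} <= supplements


def test_screen_cumulative_columns_nondecreasing(designed_screen):
    _, _, result = designed_screen
    for (supp, sp), g in result.table.groupby(["supplement", "species"]):
        g = g.sort_values("round")
        assert g["cum_degradation"].is_monotonic_increasing
        assert g["cum_supplement_consumption"].is_monotonic_increasing


def test_supplement_consumption_bounded_by_dose(designed_screen):
    _, _, result = designed_screen
    for supp, dose in result.doses.items():
        used = result.table.loc[
            result.table["supplement"] == supp, "cum_supplement_consumption"
        ].max()
        assert used <= dose + 1e-6


def test_ranking_follows_designed_yields(designed_screen):
    """Equal molar doses, disjoint menus: final community biomass orders
    supplements by their designed growth yields."""
    _, _, result = designed_screen
    ranking = rank_supplements(result, criterion="final_biomass")
    assert list(ranking["supplement"]) == ["s0_e", "s1_e", "s2_e", "s3_e"]
    assert ranking["score"].is_monotonic_decreasing


def test_ranking_ties_break_lexicographically():
    import pandas as pd

    from biostim.screening import ScreenResult

    rows = []
    for supp in ("b_e", "a_e", BASELINE_ID):
        for sp in ("sp0",):
            rows.append(
                {"supplement": supp, "species": sp, "round": 1, "biomass": 1.0,
                 "growth_flux": 0.0, "target_remaining": 50.0,
                 "supplement_remaining": 0.0, "cum_degradation": 5.0,
                 "cum_supplement_consumption": 0.0}
            )
    result = ScreenResult(pd.DataFrame(rows), "atz_e", "molar")
    ranking = rank_supplements(result, criterion="final_degradation")
    assert list(ranking["supplement"]) == ["a_e", "b_e"]


def test_unconsumable_supplement_equals_baseline(designed_screen):
    """A supplement no species can import just sits in the pool: every
    row matches the baseline trajectory."""
    models, _, result = designed_screen
    ghost = [SupplementSpec("ghost_e", "ghost", "C6H12O6")]
    res2 = screen_supplements(models, ghost, mode="molar",
                              config=SimConfig(max_rounds=15))
    base = result.table[result.table["supplement"] == BASELINE_ID]
    ghost_rows = res2.table[res2.table["supplement"] == "ghost_e"]
    merged = base.merge(ghost_rows, on=["species", "round"], suffixes=("_b", "_g"))
    assert (merged["biomass_b"] == merged["biomass_g"]).all()
    assert (merged["cum_degradation_b"] == merged["cum_degradation_g"]).all()


def test_excluded_and_elementless_candidates_skipped(designed_screen):
    models, _, _ = designed_screen
    cands = [
        SupplementSpec("s0_e", formula="C10H20O10", excluded=True),
        SupplementSpec("nh4_e", formula="H4N"),  # no carbon
    ]
    res = screen_supplements(models, cands, mode="carbon",
                             config=SimConfig(max_rounds=2))
    assert "excluded" in res.skipped["s0_e"]
    assert "not a C source" in res.skipped["nh4_e"]
    assert set(res.table["supplement"]) == {BASELINE_ID}


def test_screen_determinism_and_baseline_order_independence(designed_screen):
    models, cands, result = designed_screen
    rerun = screen_supplements(models, list(reversed(cands)), mode="molar",
                               config=SimConfig(max_rounds=15))
    assert result.table.equals(rerun.table)


def test_supplements_tsv_round_trip(tmp_path):
    specs = [
        SupplementSpec("glc_e", "glucose", "C6H12O6", False),
        SupplementSpec("tox_e", "toxin", "C2H4", True),
    ]
    path = tmp_path / "cands.tsv"
    write_supplements(specs, path)
    assert read_supplements(path) == specs
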