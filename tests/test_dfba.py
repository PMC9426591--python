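import numpy as np
import pytest

from biostim.dfba import (
    MMM_IONS,
    CommunityState,
    MediumState,
    SimConfig,
    simulate,
    step,
    uptake_bounds,
)
from biostim.formula import element_count
from biostim.synthetic import ToySpec, make_community, make_degrader


def _medium(**amounts):
    return MediumState(dict(amounts), {"hpo4_e"})


def _degrader(yield_=0.5, species="deg"):
    c = int(round(yield_ * 20))
    return make_degrader(
        ToySpec(species, ((f"glc_e", f"C{c}H{2*c}O{c}", yield_),))
    )


# -- uptake_bounds ----------------------------------------------------------

@pytest.mark.parametrize(
    "amount,total_biomass,expected",
    [(10.0, 1.0, 1.0),    # availability exceeds the per-gDW cap
     (0.5, 1.0, 0.5),     # availability-limited
     (10.0, 4.0, 1.0)],   # min(1, 10/4) = 1; aggregate draw 4 <= 10
)
def test_uptake_caps(amount, total_biomass, expected):
    caps = uptake_bounds(_medium(glc_e=amount), total_biomass, SimConfig())
    assert caps["glc_e"] == pytest.approx(expected)


def test_unlimited_ions_capped_at_vmax_only():
    caps = uptake_bounds(_medium(glc_e=0.001), 10.0, SimConfig(vmax=2.0))
    assert caps["hpo4_e"] == 2.0
    assert caps["glc_e"] == pytest.approx(0.0001)


def test_uptake_bounds_rejects_nonpositive_biomass():
    with pytest.raises(ValueError, match="positive"):
        uptake_bounds(_medium(glc_e=1.0), 0.0, SimConfig())


# -- step -------------------------------------------------------------------

def test_step_single_species_hand_values():
    """yield 0.5, X=1, A=10, vmax=1: mu=0.5, X'=1.5, consumption 1 -> A'=9."""
    model = _degrader()
    state = CommunityState({"deg": 1.0}, _medium(glc_e=10.0))
    new, recs = step([model], state, SimConfig())
    assert new.biomass["deg"] == pytest.approx(1.5, abs=1e-8)
    assert new.medium.amounts["glc_e"] == pytest.approx(9.0, abs=1e-8)
    assert recs[0]["growth_flux"] == pytest.approx(0.5, abs=1e-9)


def test_step_empty_pool_is_fixed_point():
    model = _degrader()
    state = CommunityState({"deg": 1.0}, _medium(glc_e=0.0))
    new, _ = step([model], state, SimConfig())
    assert new.biomass["deg"] == 1.0
    assert new.medium.amounts["glc_e"] == 0.0


def test_step_two_identical_species_split_symmetrically():
    """Caps use TOTAL biomass: each of two identical species gets
    min(1, 10/2)=1, grows to 1.5, and the pool drops by 2."""
    m1, m2 = _degrader(species="sp_a"), _degrader(species="sp_b")
    state = CommunityState({"sp_a": 1.0, "sp_b": 1.0}, _medium(glc_e=10.0))
    new, _ = step([m1, m2], state, SimConfig())
    assert new.biomass["sp_a"] == pytest.approx(1.5, abs=1e-8)
    assert new.biomass["sp_b"] == pytest.approx(1.5, abs=1e-8)
    assert new.medium.amounts["glc_e"] == pytest.approx(8.0, abs=1e-8)


def test_step_round_index_increments():
    model = _degrader()
    state = CommunityState({"deg": 1.0}, _medium(glc_e=1.0), round_index=4)
    new, recs = step([model], state, SimConfig())
    assert new.round_index == 5
    assert recs[0]["round"] == 5


# -- simulate ---------------------------------------------------------------

def test_simulate_converges_after_exhaustion():
    """A0=1, X0=1, yield 0.5: one productive round (X=1.5, A exhausted),
    then a zero-growth round triggers convergence."""
    traj = simulate([_degrader()], _medium(glc_e=1.0))
    assert traj.n_rounds == 2
    assert traj.final_state.biomass["deg"] == pytest.approx(1.5, abs=1e-8)
    assert traj.final_state.medium.amounts["glc_e"] == pytest.approx(0.0, abs=1e-8)


def test_simulate_empty_pool_short_trajectory():
    traj = simulate([_degrader()], _medium(glc_e=0.0))
    assert traj.n_rounds <= 2
    assert all(s.biomass["deg"] == 1.0 for s in traj.states)


def test_simulate_is_deterministic():
    t1 = simulate([_degrader()], _medium(glc_e=7.0))
    t2 = simulate([_degrader()], _medium(glc_e=7.0))
    assert [s.biomass for s in t1.states] == [s.biomass for s in t2.states]
    assert [s.medium.amounts for s in t1.states] == [s.medium.amounts for s in t2.states]


def test_linear_chain_matches_closed_form_recursion():
    """simulate() must reproduce X_{t+1} = X_t (1 + Y min(vmax, A_t/X_t)),
    A_{t+1} = A_t - X_t min(vmax, A_t/X_t) to LP tolerance."""
    y, a0, vmax = 0.45, 12.0, 1.0
    config = SimConfig(vmax=vmax, max_rounds=12)
    traj = simulate([_degrader(yield_=y)], _medium(glc_e=a0), config)
    x, a = 1.0, a0
    for state in traj.states[1:]:
        u = min(vmax, a / x)
        x, a = x * (1 + y * u), a - x * u  # consumption scales with old X
        assert state.biomass["deg"] == pytest.approx(x, abs=1e-6)
        assert state.medium.amounts["glc_e"] == pytest.approx(a, abs=1e-6)


def test_dose_monotonicity():
    """More supplement never means less final biomass on monotone toys."""
    finals = [
        simulate([_degrader()], _medium(glc_e=dose)).final_state.total_biomass
        for dose in (0.0, 1.0, 5.0, 25.0)
    ]
    assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(finals, finals[1:]))


def test_nonconsumer_biomass_constant_in_community(designed_community):
    """A species with no transporter for anything in the pool keeps its
    LP optimum at 0 every round."""
    medium = MediumState({"s0_e": 20.0, "atz_e": 50.0}, set(MMM_IONS))
    traj = simulate(designed_community, medium, SimConfig(max_rounds=6))
    for sp in ("sp1", "sp2", "sp3"):  # only sp0 eats s0/atz
        assert all(s.biomass[sp] == pytest.approx(1.0) for s in traj.states)


def test_biomass_nondecreasing_and_pool_nonnegative():
    rng = np.random.default_rng(42)
    for _ in range(10):
        n = int(rng.integers(1, 4))
        overlap = rng.random((n, n)) < 0.6
        overlap[np.arange(n), np.arange(n)] = True
        models = make_community(n, overlap, seed=int(rng.integers(2**31)))
        amounts = {f"s{j}_e": float(rng.uniform(0, 30)) for j in range(n)}
        amounts["atz_e"] = float(rng.uniform(5, 50))
        traj = simulate(models, MediumState(amounts, set(MMM_IONS)),
                        SimConfig(max_rounds=5))
        for prev, cur in zip(traj.states, traj.states[1:]):
            for sp in cur.biomass:
                assert cur.biomass[sp] >= prev.biomass[sp] - 1e-9
            assert all(v >= 0.0 for v in cur.medium.amounts.values())


def test_carbon_conservation_on_balanced_community():
    """Finite-pool carbon plus biomass carbon (20 mmol C/gDW by generator
    declaration) is constant each round when every conversion is
    carbon-balanced by construction."""
    models = make_community(3, seed=5)
    formulas = {}
    for m in models:
        formulas.update({met.id: met.formula for met in m.metabolites})
    amounts = {"s0_e": 10.0, "s1_e": 8.0, "s2_e": 6.0, "atz_e": 20.0}
    traj = simulate(models, MediumState(dict(amounts), set(MMM_IONS)),
                    SimConfig(max_rounds=8))

    def total_carbon(state):
        pool = sum(
            amt * element_count(formulas[met], "C")
            for met, amt in state.medium.amounts.items()
        )
        biomass = sum(state.biomass.values()) * models[0].metadata["biomass_carbon"]
        return pool + biomass

    c0 = total_carbon(traj.states[0])
    for state in traj.states[1:]:
        assert total_carbon(state) == pytest.approx(c0, abs=1e-6 * max(1.0, c0))


def test_additive_update_flag():
    traj = simulate([_degrader()], _medium(glc_e=10.0),
                    SimConfig(max_rounds=1, biomass_update="additive"))
    # additive: X' = X + mu = 1 + 0.5
    assert traj.final_state.biomass["deg"] == pytest.approx(1.5, abs=1e-8)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(vmax=0)
    with pytest.raises(ValueError):
        SimConfig(max_rounds=0)
    with pytest.raises(ValueError):
        SimConfig(biomass_update="exponential")
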