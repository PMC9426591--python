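"""Iterative dynamic FBA for one species or a community sharing a finite pool.

The simulation discretizes growth into rounds. Each round:

1. Per-gDW uptake caps are derived from the shared pool: a species may draw
   at most ``min(vmax, available / total_biomass)`` of each finite
   metabolite, so aggregate draw never exceeds availability no matter how
   many species compete. Mineral ions declared unlimited are capped at
   ``vmax`` only.
2. Every species solves its own FBA against the same pool snapshot
   (simultaneous, order-independent).
3. Biomass is updated from the optimal growth flux mu (multiplicative Euler
   step ``X <- X * (1 + mu)`` with a 1-round tick), and the pool is updated
   with each species' net exchange fluxes scaled by its pre-update biomass.

Rounds repeat until the relative increase of total biomass falls below a
tolerance or a maximum round count is reached. There is no death or
maintenance term, so biomass is non-decreasing and the fixed point is
starvation, not steady-state turnover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fba import solve_fba
from .model import MetabolicModel

__all__ = [
    "MediumState",
    "CommunityState",
    "SimConfig",
    "Trajectory",
    "uptake_bounds",
    "step",
    "simulate",
]

#: MMM — the background minimal mineral medium: inorganic ions (plus CO2)
#: treated as inexhaustible; only carbon/nitrogen sources are dosed finitely.
MMM_IONS = (
    "k_e", "mn2_e", "co2_e", "zn2_e", "so4_e", "cu2_e",
    "ca2_e", "hpo4_e", "mg2_e", "fe2_e", "cl_e",
)


@dataclass
class MediumState:
    """Finite extracellular pool (mmol per gDW basis) plus unlimited ions."""

    amounts: dict[str, float] = field(default_factory=dict)
    unlimited: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for met, amt in self.amounts.items():
            if amt < 0:
                raise ValueError(f"negative medium amount for {met!r}: {amt}")
        overlap = set(self.amounts) & self.unlimited
        if overlap:
            raise ValueError(
                f"metabolites cannot be both finite and unlimited: {sorted(overlap)}"
            )

    def copy(self) -> "MediumState":
        return MediumState(dict(self.amounts), set(self.unlimited))


@dataclass
class CommunityState:
    biomass: dict[str, float]
    medium: MediumState
    round_index: int = 0

    def __post_init__(self) -> None:
        for sp, x in self.biomass.items():
            if x <= 0:
                raise ValueError(f"non-positive biomass for species {sp!r}: {x}")

    @property
    def total_biomass(self) -> float:
        return sum(self.biomass.values())


@dataclass
class SimConfig:
    """Simulation knobs.

    vmax
        Per-biomass uptake cap, mmol·gDW⁻¹·round⁻¹ (default 1: at most one
        unit of each available metabolite per unit of biomass per round).
    max_rounds
        Hard stop (default 15 rounds).
    convergence_tol
        Stop when the relative total-biomass increase in a round falls
        below this (default 1e-6).
    initial_biomass
        Starting biomass per species, gDW (default 1, equal for all
        species — the simulations are qualitative and start symmetric).
    biomass_update
        "multiplicative" (default): X <- X*(1+mu); "additive": X <- X+mu.
    tie_break
        FBA alternate-optimum rule passed through to the solver
        ("pfba" or "none").
    """

    vmax: float = 1.0
    max_rounds: int = 15
    convergence_tol: float = 1e-6
    initial_biomass: float = 1.0
    biomass_update: str = "multiplicative"
    tie_break: str = "pfba"

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.convergence_tol <= 0 or self.initial_biomass <= 0:
            raise ValueError("vmax, convergence_tol and initial_biomass must be positive")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.biomass_update not in ("multiplicative", "additive"):
            raise ValueError(f"unknown biomass_update {self.biomass_update!r}")


@dataclass
class Trajectory:
    """Per-round history: community states plus per-species flux records."""

    states: list[CommunityState]
    records: list[dict]  # keys: round, species, biomass, growth_flux, exchange

    @property
    def final_state(self) -> CommunityState:
        return self.states[-1]

    @property
    def n_rounds(self) -> int:
        return self.states[-1].round_index

    def biomass_series(self, species_id: str) -> list[float]:
        return [s.biomass[species_id] for s in self.states]

    def pool_series(self, metabolite_id: str) -> list[float]:
        return [s.medium.amounts.get(metabolite_id, 0.0) for s in self.states]

    def consumed(self, metabolite_id: str, round_index: int | None = None) -> float:
        """Cumulative net removal of a pool metabolite up to a round
        (defaults to the final round); this is the degradation readout
        when applied to the target compound."""
        if round_index is None:
            round_index = self.n_rounds
        round_index = min(round_index, self.n_rounds)
        start = self.states[0].medium.amounts.get(metabolite_id, 0.0)
        now = self.states[round_index].medium.amounts.get(metabolite_id, 0.0)
        return start - now

    def biomass_at(self, species_id: str, round_index: int) -> float:
        """Biomass of a species at a round; constant after convergence, so
        rounds past the end of the trajectory return the final value."""
        round_index = min(round_index, self.n_rounds)
        return self.states[round_index].biomass[species_id]


def uptake_bounds(
    medium: MediumState, total_biomass: float, config: SimConfig
) -> dict[str, float]:
    """Per-gDW uptake cap for every metabolite present in the medium.

    cap = min(vmax, available / total_biomass) for finite metabolites,
    vmax for unlimited ions. Metabolites absent from the medium get no
    entry (their uptake stays closed).
    """
    if total_biomass <= 0:
        raise ValueError(f"total biomass must be positive, got {total_biomass}")
    caps = {
        met: min(config.vmax, amount / total_biomass)
        for met, amount in medium.amounts.items()
    }
    caps.update({met: config.vmax for met in medium.unlimited})
    return caps


def _exchange_overrides(
    model: MetabolicModel, caps: dict[str, float]
) -> tuple[dict[str, tuple[float, float]], dict[str, str]]:
    """Exchange-bound overrides for one species given the medium caps.

    Absent metabolites close to zero uptake (LP stays feasible with zero
    growth — starvation is not an error). A static lower bound of 0 is
    never opened: irreversible secretion-only exchanges stay that way.
    Returns (overrides, exchange reaction id -> metabolite id).
    """
    overrides: dict[str, tuple[float, float]] = {}
    ex_met: dict[str, str] = {}
    for r in model.reactions:
        if not r.is_exchange:
            continue
        met = next(iter(r.stoichiometry))
        ex_met[r.id] = met
        cap = caps.get(met, 0.0)
        lb = max(r.lower_bound, -cap)
        overrides[r.id] = (min(lb, r.upper_bound), r.upper_bound)
    return overrides, ex_met


def step(
    models: list[MetabolicModel],
    state: CommunityState,
    config: SimConfig,
) -> tuple[CommunityState, list[dict]]:
    """Advance the community by one round against the current pool snapshot."""
    if {m.species_id for m in models} != set(state.biomass):
        raise ValueError("models do not match the species in the community state")
    caps = uptake_bounds(state.medium, state.total_biomass, config)

    new_biomass: dict[str, float] = {}
    deltas: dict[str, float] = {}
    records: list[dict] = []
    rnd = state.round_index + 1
    for model in models:
        sp = model.species_id
        overrides, ex_met = _exchange_overrides(model, caps)
        sol = solve_fba(model, overrides, tie_break=config.tie_break)
        if not sol.ok:
            raise RuntimeError(
                f"FBA {sol.status} for species {sp!r} at round {rnd}"
            )
        mu = max(sol.objective_value, 0.0)  # no death term
        x_old = state.biomass[sp]
        if config.biomass_update == "multiplicative":
            new_biomass[sp] = x_old * (1.0 + mu)
        else:
            new_biomass[sp] = x_old + mu
        exchange = {}
        for rid, met in ex_met.items():
            flux = sol.fluxes[rid]
            exchange[met] = flux
            if met not in state.medium.unlimited:
                # negative flux = uptake, drains the pool
                deltas[met] = deltas.get(met, 0.0) + flux * x_old
        records.append(
            {"round": rnd, "species": sp, "biomass": new_biomass[sp],
             "growth_flux": mu, "exchange": exchange}
        )

    new_amounts = dict(state.medium.amounts)
    clamp_tol = 1e-9 * max(1.0, state.total_biomass)
    for met, delta in deltas.items():
        amt = new_amounts.get(met, 0.0) + delta
        if amt < -clamp_tol:
            raise RuntimeError(
                f"pool went negative for {met!r} at round {rnd}: {amt}"
            )
        new_amounts[met] = max(amt, 0.0)

    new_state = CommunityState(
        biomass=new_biomass,
        medium=MediumState(new_amounts, set(state.medium.unlimited)),
        round_index=rnd,
    )
    return new_state, records


def simulate(
    models: list[MetabolicModel],
    medium0: MediumState,
    config: SimConfig | None = None,
) -> Trajectory:
    """Run the round loop from equal initial biomass until growth stalls.

    Stops when the relative total-biomass increase of a round drops below
    ``config.convergence_tol`` or after ``config.max_rounds`` rounds. A
    single-species community follows the identical code path.
    """
    if config is None:
        config = SimConfig()
    if not models:
        raise ValueError("at least one species model is required")
    ids = [m.species_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species ids: {ids}")
    for m in models:
        m.validate()

    state = CommunityState(
        biomass={sp: config.initial_biomass for sp in ids},
        medium=medium0.copy(),
        round_index=0,
    )
    states = [state]
    records: list[dict] = []
    for _ in range(config.max_rounds):
        total_old = state.total_biomass
        state, round_records = step(models, state, config)
        states.append(state)
        records.extend(round_records)
        rel_gain = (state.total_biomass - total_old) / total_old
        if rel_gain < config.convergence_tol:
            break
    return Trajectory(states=states, records=records)
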