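"""Steady-state flux balance analysis (FBA) and flux variability analysis (FVA).

FBA solves::

    max  v_biomass
    s.t. S v = 0          (steady state: no net internal accumulation)
         lb <= v <= ub    (static bounds, overridden per round by the
                           dynamic simulation)

The optimal flux vector is generally non-unique. The dynamic loop needs one
deterministic vector per tick, so after fixing the biomass flux at its
optimum a parsimonious secondary LP minimizes the sum of absolute fluxes
(pFBA); FVA reports the min/max flux per reaction at a fraction of the
optimum and is the tool for inspecting the remaining degrees of freedom.

The LP solver is an injected contract (``solver(c, A_eq, b_eq, A_ub, b_ub,
bounds) -> (status, x)``); the default wraps scipy's HiGHS interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "solve_fba",
    "solve_fva",
    "scipy_highs_solver",
    "stoichiometric_matrix",
]

#: LP-level feasibility/optimality tolerance (solver); model-level
#: assertions use the looser 1e-6 to separate solver noise from logic errors.
LP_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    """One FBA solution; ``objective_value`` is NaN unless status is optimal."""

    objective_value: float
    fluxes: dict[str, float]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def scipy_highs_solver(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    return _STATUS.get(res.status, "numerical"), (res.x if res.status == 0 else None)


def stoichiometric_matrix(model: MetabolicModel):
    """(S, metabolite ids, reaction ids) with S[i, j] the coefficient of
    metabolite i in reaction j."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for met_id, coeff in r.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return S, [m.id for m in model.metabolites], [r.id for r in model.reactions]


def _effective_bounds(model, bound_overrides):
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if bound_overrides:
        idx = {r.id: j for j, r in enumerate(model.reactions)}
        for rid, (lb, ub) in bound_overrides.items():
            if rid not in idx:
                raise KeyError(f"bound override for unknown reaction {rid!r}")
            if lb > ub:
                raise ValueError(f"override for {rid!r}: lb {lb} > ub {ub}")
            bounds[idx[rid]] = (lb, ub)
    return bounds


def solve_fba(
    model: MetabolicModel,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
    tie_break: str = "pfba",
    solver=scipy_highs_solver,
) -> FluxSolution:
    """Maximize biomass flux; report an infeasible LP faithfully.

    ``tie_break="pfba"`` (default) re-solves with biomass fixed at its
    optimum, minimizing the sum of absolute fluxes, so alternate optima map
    to one deterministic vector; ``tie_break="none"`` returns the raw
    solver vertex.
    """
    if tie_break not in ("pfba", "none"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    S, _, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    bounds = _effective_bounds(model, bound_overrides)
    bio_j = rxn_ids.index(model.biomass_reaction.id)

    c = np.zeros(n)
    c[bio_j] = -1.0  # linprog minimizes
    b_eq = np.zeros(S.shape[0])
    status, x = solver(c, S, b_eq, None, None, bounds)
    if status != "optimal":
        return FluxSolution(math.nan, {}, status)
    opt = x[bio_j]

    if tie_break == "pfba":
        x_p = _parsimonious(S, bounds, bio_j, opt, solver)
        if x_p is not None:
            x = x_p

    return FluxSolution(float(opt), dict(zip(rxn_ids, map(float, x))), "optimal")


def _parsimonious(S, bounds, bio_j, opt, solver):
    """min sum|v| s.t. S v = 0, bounds, v_bio pinned at the optimum."""
    n = S.shape[1]
    bounds2 = list(bounds)
    slack = max(abs(opt), 1.0) * 1e-9
    bounds2[bio_j] = (opt - slack, max(opt, bounds[bio_j][1]))
    # variables [v; t], t_j >= |v_j|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sparse.hstack([S, sparse.csr_matrix(S.shape)])
    b_eq = np.zeros(S.shape[0])
    eye = sparse.identity(n)
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])])
    b_ub = np.zeros(2 * n)
    t_bounds = [(0, max(abs(lo), abs(hi))) for lo, hi in bounds2]
    status, x = solver(c, A_eq, b_eq, A_ub, b_ub, bounds2 + t_bounds)
    if status != "optimal":
        return None  # fall back to the raw vertex
    return x[:n]


def solve_fva(
    model: MetabolicModel,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
    objective_fraction: float = 1.0,
    reactions: list[str] | None = None,
    solver=scipy_highs_solver,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range with biomass held at >= fraction x optimum."""
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    base = solve_fba(model, bound_overrides, tie_break="none", solver=solver)
    if not base.ok:
        raise RuntimeError(f"FVA base problem not optimal: status={base.status}")
    S, _, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    bounds = _effective_bounds(model, bound_overrides)
    bio_j = rxn_ids.index(model.biomass_reaction.id)
    # relax the floor by the LP tolerance so the optimum itself stays feasible
    floor = objective_fraction * base.objective_value
    floor -= max(abs(floor), 1.0) * 1e-9
    lo, hi = bounds[bio_j]
    bounds = list(bounds)
    bounds[bio_j] = (max(lo, floor), hi)

    targets = reactions if reactions is not None else rxn_ids
    b_eq = np.zeros(S.shape[0])
    ranges = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        st_min, x_min = solver(c, S, b_eq, None, None, bounds)
        st_max, x_max = solver(-c, S, b_eq, None, None, bounds)
        if st_min != "optimal" or st_max != "optimal":
            raise RuntimeError(f"FVA subproblem for {rid!r} not optimal")
        ranges[rid] = (float(x_min[j]), float(x_max[j]))
    return ranges
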