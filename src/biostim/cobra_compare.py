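"""Optional interop with cobrapy for independent cross-validation.

Converts a :class:`~biostim.model.MetabolicModel` into a cobrapy model so
the built-in FBA engine can be checked against a second, independently
implemented constraint-based solver stack. Requires the optional ``cobra``
dependency (``pip install biostim[test]``); imports lazily so the core
package works without it.
"""

from __future__ import annotations

from .model import EXTRACELLULAR, MetabolicModel

__all__ = ["to_cobra", "reference_objective"]


def to_cobra(model: MetabolicModel,
             bound_overrides: dict[str, tuple[float, float]] | None = None):
    """Build an equivalent cobrapy model (optionally with bound overrides)."""
    import cobra

    cm = cobra.Model(model.species_id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name,
            compartment="e" if m.compartment == EXTRACELLULAR else "c",
        )
        for m in model.metabolites
    }
    overrides = bound_overrides or {}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        lb, ub = overrides.get(r.id, (r.lower_bound, r.upper_bound))
        rxns.append(cr)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        cr.lower_bound, cr.upper_bound = lb, ub
    cm.add_reactions(rxns)
    cm.objective = model.biomass_reaction.id
    return cm


def reference_objective(model: MetabolicModel,
                        bound_overrides: dict[str, tuple[float, float]] | None = None
                        ) -> float:
    """Optimal biomass flux according to cobrapy (0.0 for an infeasible LP
    is never silently returned; cobra raises on infeasibility via NaN)."""
    cm = to_cobra(model, bound_overrides)
    value = cm.slim_optimize()
    return float(value)
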