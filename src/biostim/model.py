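"""Constraint-based model containers.

A :class:`MetabolicModel` is a stoichiometric network with flux bounds, a
designated biomass reaction (the growth objective) and a designated
degradation target — the extracellular pollutant whose removal the
simulations track. Exchange reactions follow the COBRA convention:
a pseudo-reaction touching exactly one extracellular metabolite with
coefficient -1, so negative flux is uptake and positive flux secretion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .formula import parse_formula

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "DEFAULT_BOUND",
]

DEFAULT_BOUND = 1000.0  # conventional "unbounded" flux magnitude

CYTOSOL = "cytosol"
EXTRACELLULAR = "extracellular"


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""  # Hill-style element counts; "" = unknown composition
    compartment: str = CYTOSOL

    def __post_init__(self) -> None:
        if self.compartment not in (CYTOSOL, EXTRACELLULAR):
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        parse_formula(self.formula)  # raises FormulaError if malformed


@dataclass(frozen=True)
class Reaction:
    """One reaction; stoichiometry maps metabolite id -> signed coefficient.

    Bounds are fluxes in mmol·gDW⁻¹·round⁻¹ (biomass reaction:
    gDW·gDW⁻¹·round⁻¹).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    """A species-level stoichiometric network.

    ``degradation_target`` names the extracellular metabolite whose
    consumption is the degradation readout (e.g. atrazine); it may be None
    for species with no degradation pathway. ``metadata`` carries free-form
    keys; the synthetic-model generator stores ``biomass_carbon`` (mmol C
    per gDW of biomass) there so elemental-balance checks have ground truth.
    """

    species_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    degradation_target: str | None = None
    metadata: dict = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_ids(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def biomass_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.is_biomass:
                return r
        raise ModelValidationError(f"model {self.species_id!r}: no biomass reaction")

    def exchange_reaction_for(self, metabolite_id: str) -> Reaction | None:
        """The exchange reaction of an extracellular metabolite, if any."""
        for r in self.reactions:
            if r.is_exchange and metabolite_id in r.stoichiometry:
                return r
        return None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise ModelValidationError."""
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(
                f"model {self.species_id!r}: duplicate metabolite ids {dup}"
            )
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(
                f"model {self.species_id!r}: duplicate reaction ids {dup}"
            )
        known = set(met_ids)
        by_id = self.metabolite_ids
        n_biomass = 0
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites "
                    f"{sorted(missing)}"
                )
            if r.is_biomass:
                n_biomass += 1
            if r.is_exchange:
                ext = [
                    m for m in r.stoichiometry
                    if by_id[m].compartment == EXTRACELLULAR
                ]
                if (
                    len(r.stoichiometry) != 1
                    or len(ext) != 1
                    or r.stoichiometry[ext[0]] != -1
                ):
                    raise ModelValidationError(
                        f"exchange reaction {r.id!r} must touch exactly one "
                        f"extracellular metabolite with coefficient -1"
                    )
        if n_biomass != 1:
            raise ModelValidationError(
                f"model {self.species_id!r}: expected exactly one biomass "
                f"reaction, found {n_biomass}"
            )
        if self.degradation_target is not None:
            if self.degradation_target not in known:
                raise ModelValidationError(
                    f"degradation target {self.degradation_target!r} is not a "
                    f"declared metabolite"
                )
            if self.exchange_reaction_for(self.degradation_target) is None:
                raise ModelValidationError(
                    f"degradation target {self.degradation_target!r} has no "
                    f"exchange reaction"
                )

    # -- queries -----------------------------------------------------------

    def exchange_metabolites(self) -> list[str]:
        """Extracellular metabolite ids with an exchange reaction, sorted.

        These are the species' interface with the shared medium — the
        candidate pool for supplement screens.
        """
        self.validate()
        ids = set()
        for r in self.reactions:
            if r.is_exchange:
                ids.add(next(iter(r.stoichiometry)))
        return sorted(ids)

    def with_bounds(self, overrides: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with per-reaction (lb, ub) overrides applied."""
        known = self.reaction_ids
        unknown = set(overrides) - set(known)
        if unknown:
            raise KeyError(f"bound overrides for unknown reactions {sorted(unknown)}")
        new_rxns = []
        for r in self.reactions:
            if r.id in overrides:
                lb, ub = overrides[r.id]
                new_rxns.append(replace(r, lower_bound=lb, upper_bound=ub))
            else:
                new_rxns.append(r)
        return MetabolicModel(
            species_id=self.species_id,
            metabolites=list(self.metabolites),
            reactions=new_rxns,
            degradation_target=self.degradation_target,
            metadata=dict(self.metadata),
        )


def exchange_metabolites(model: MetabolicModel) -> list[str]:
    """Module-level alias of :meth:`MetabolicModel.exchange_metabolites`."""
    return model.exchange_metabolites()
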