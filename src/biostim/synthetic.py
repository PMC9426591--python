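"""Generator of small, fully specified metabolic models and communities.

Real genome-scale reconstructions are thousands of reactions with opaque
biomass equations; these toys keep the same structure the screening pipeline
assumes — exchange reactions, species-specific supplement transporters, an
atrazine-like degradation pathway and a single biomass objective — at a size
where every expected number is computable by hand.

Construction scheme, per supplement ``s`` in a species' menu::

    EX_s:    s_e <->            (exchange; uptake capped per round)
    T_s:     s_e -> s_c         (transport)
    CONV_s:  s_c -> Y_s bm_c    (catabolism into biomass precursor)
    BIOMASS: bm_c + 0.05 hpo4_c ->  (objective; 1 gDW per unit flux)

so FBA growth on sole supplement ``s`` at uptake cap ``v`` is exactly
``Y_s * v``. Degraders additionally carry ``EX_atz / T_atz / DEG_atz`` with
``DEG_atz: atz_c -> target_yield * bm_c``. The biomass precursor carries 20
carbon atoms per unit, declared in model metadata as ``biomass_carbon``, so
elemental balance has ground truth: carbon is conserved exactly whenever
supplement carbon counts satisfy ``C(s) = Y_s * 20`` (the generator draws
carbon counts in 2..12 and sets ``Y_s = C(s)/20``; the C8 atrazine-like
target balances at target_yield 8/20 = 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CYTOSOL, EXTRACELLULAR, MetabolicModel, Metabolite, Reaction
from .screening import SupplementSpec

__all__ = [
    "ToySpec",
    "make_degrader",
    "make_community",
    "make_observation_table",
    "community_supplement_specs",
    "BIOMASS_CARBON",
    "TARGET_ID",
    "TARGET_FORMULA",
    "TARGET_YIELD",
]

BIOMASS_CARBON = 20          # mmol C per gDW of biomass (via the bm_c precursor)
TARGET_ID = "atz_e"          # atrazine-like degradation target
TARGET_FORMULA = "C8H14ClN5"
TARGET_YIELD = 8 / BIOMASS_CARBON  # carbon-balanced growth yield on the target
_PI_COEFF = 0.05             # phosphate demand per unit biomass flux


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one toy species.

    ``supplement_menu`` lists (extracellular metabolite id, formula,
    biomass yield Y in gDW per mmol) for every supplement the species can
    import. Yields must be non-negative; the id convention is a ``_e``
    suffix (added if missing).
    """

    species_id: str
    supplement_menu: tuple[tuple[str, str, float], ...]
    degrades_target: bool = False
    target_yield: float = TARGET_YIELD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_yield < 0:
            raise ValueError("target_yield must be >= 0")
        for _, _, y in self.supplement_menu:
            if y < 0:
                raise ValueError("supplement yields must be >= 0")


def _stem(met_id: str) -> str:
    return met_id[:-2] if met_id.endswith("_e") else met_id


def make_degrader(spec: ToySpec) -> MetabolicModel:
    """Build one toy species from its recipe; deterministic, validates."""
    mets: list[Metabolite] = [
        Metabolite("bm_c", "biomass precursor", f"C{BIOMASS_CARBON}H38O10", CYTOSOL),
        Metabolite("hpo4_e", "phosphate", "HO4P", EXTRACELLULAR),
        Metabolite("hpo4_c", "phosphate", "HO4P", CYTOSOL),
    ]
    rxns: list[Reaction] = [
        Reaction("EX_hpo4", {"hpo4_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        Reaction("T_hpo4", {"hpo4_e": -1.0, "hpo4_c": 1.0}, 0.0, 1000.0),
        Reaction(
            "BIOMASS",
            {"bm_c": -1.0, "hpo4_c": -_PI_COEFF},
            0.0,
            1000.0,
            is_biomass=True,
        ),
    ]
    yields: dict[str, float] = {}
    seen: set[str] = set()
    for met_id, formula, y in spec.supplement_menu:
        stem = _stem(met_id)
        ext = f"{stem}_e"
        if ext in seen or ext == TARGET_ID:
            raise ValueError(f"duplicate or reserved supplement id {ext!r}")
        seen.add(ext)
        mets.append(Metabolite(ext, stem, formula, EXTRACELLULAR))
        mets.append(Metabolite(f"{stem}_c", stem, formula, CYTOSOL))
        rxns.append(Reaction(f"EX_{stem}", {ext: -1.0}, -1000.0, 1000.0, is_exchange=True))
        rxns.append(Reaction(f"T_{stem}", {ext: -1.0, f"{stem}_c": 1.0}, 0.0, 1000.0))
        rxns.append(Reaction(f"CONV_{stem}", {f"{stem}_c": -1.0, "bm_c": y}, 0.0, 1000.0))
        yields[ext] = y

    if spec.degrades_target:
        mets.append(Metabolite(TARGET_ID, "atrazine-like target", TARGET_FORMULA, EXTRACELLULAR))
        mets.append(Metabolite("atz_c", "atrazine-like target", TARGET_FORMULA, CYTOSOL))
        rxns.append(Reaction("EX_atz", {TARGET_ID: -1.0}, -1000.0, 1000.0, is_exchange=True))
        rxns.append(Reaction("T_atz", {TARGET_ID: -1.0, "atz_c": 1.0}, 0.0, 1000.0))
        rxns.append(
            Reaction("DEG_atz", {"atz_c": -1.0, "bm_c": spec.target_yield}, 0.0, 1000.0)
        )
        yields[TARGET_ID] = spec.target_yield

    model = MetabolicModel(
        species_id=spec.species_id,
        metabolites=mets,
        reactions=rxns,
        degradation_target=TARGET_ID if spec.degrades_target else None,
        metadata={
            "biomass_carbon": float(BIOMASS_CARBON),
            "supplement_yields": yields,
            "seed": spec.seed,
        },
    )
    model.validate()
    return model


def make_community(
    n_species: int,
    menu_overlap: np.ndarray | list[list[bool]] | None = None,
    seed: int = 0,
    degraders: list[bool] | None = None,
) -> list[MetabolicModel]:
    """Generate ``n_species`` toy models sharing a supplement universe.

    ``menu_overlap`` is a species x supplement boolean matrix saying which
    species can import which supplement (default: identity — disjoint
    menus, one private supplement per species). Supplement carbon counts
    are drawn without replacement from 2..12 with the seeded generator, so
    yields ``C/20`` are distinct across supplements and identical seeds
    give identical communities. At least one species must degrade the
    target (default: the first).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    overlap = (
        np.eye(n_species, dtype=bool)
        if menu_overlap is None
        else np.asarray(menu_overlap, dtype=bool)
    )
    if overlap.ndim != 2 or overlap.shape[0] != n_species:
        raise ValueError(
            f"menu_overlap must have {n_species} rows, got shape {overlap.shape}"
        )
    empty = [i for i in range(n_species) if not overlap[i].any()]
    if empty:
        raise ValueError(f"species rows with empty menus (eat nothing): {empty}")
    if degraders is None:
        degraders = [i == 0 for i in range(n_species)]
    if len(degraders) != n_species or not any(degraders):
        raise ValueError("degraders must flag at least one of the species")

    n_supp = overlap.shape[1]
    if n_supp > 11:
        raise ValueError("at most 11 supplements (distinct carbon counts in 2..12)")
    rng = np.random.default_rng(seed)
    carbons = rng.choice(np.arange(2, 13), size=n_supp, replace=False)
    menu_items = [
        (f"s{j}_e", f"C{int(c)}H{2 * int(c)}O{int(c)}", int(c) / BIOMASS_CARBON)
        for j, c in enumerate(carbons)
    ]
    models = []
    for i in range(n_species):
        spec = ToySpec(
            species_id=f"sp{i}",
            supplement_menu=tuple(menu_items[j] for j in range(n_supp) if overlap[i, j]),
            degrades_target=bool(degraders[i]),
            seed=seed,
        )
        models.append(make_degrader(spec))
    return models


def community_supplement_specs(models: list[MetabolicModel]) -> list[SupplementSpec]:
    """Candidate list covering every supplement any community member eats
    (union of the generator-declared menus, target excluded), with formulas
    taken from the metabolite records."""
    specs: dict[str, SupplementSpec] = {}
    for m in models:
        formulas = {met.id: met.formula for met in m.metabolites}
        for met_id in m.metadata.get("supplement_yields", {}):
            if met_id == m.degradation_target or met_id in specs:
                continue
            specs[met_id] = SupplementSpec(
                id=met_id, name=_stem(met_id), formula=formulas[met_id]
            )
    return [specs[k] for k in sorted(specs)]


def make_observation_table(
    pred: pd.DataFrame, flip_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Synthetic ground truth: flip each prediction cell independently with
    probability ``flip_rate`` (0 reproduces the predictions, 1 inverts
    them), using a seeded generator."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError(f"flip_rate must lie in [0, 1], got {flip_rate}")
    rng = np.random.default_rng(seed)
    flips = rng.random(pred.shape) < flip_rate
    obs = pred.astype(bool) ^ flips
    obs.attrs["flip_rate"] = flip_rate
    obs.attrs["seed"] = seed
    return obs
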