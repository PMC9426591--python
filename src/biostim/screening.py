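"""Supplement screening: dosed media, the supplement x species grid, ranking.

A screen runs one community simulation per candidate supplement plus a
no-supplement baseline, all in the same minimal mineral background with a
fixed dose of the degradation target. Doses can be equimolar or normalized
so every candidate delivers the same molar carbon (or nitrogen) as a
reference compound — e.g. at a glucose reference of 50 mmol/gDW, a C12
disaccharide is dosed at 25 and a C18 fatty acid at floor(300/18) = 16.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dfba import MMM_IONS, MediumState, SimConfig, Trajectory, simulate
from .formula import element_count
from .model import MetabolicModel

__all__ = [
    "SupplementSpec",
    "ScreenResult",
    "carbon_normalized_dose",
    "nitrogen_normalized_dose",
    "normalized_dose",
    "build_medium",
    "screen_supplements",
    "rank_supplements",
    "read_supplements",
    "write_supplements",
    "GLUCOSE_FORMULA",
    "ATRAZINE_FORMULA",
    "BASELINE_ID",
]

log = logging.getLogger(__name__)

GLUCOSE_FORMULA = "C6H12O6"    # default carbon-normalization reference
ATRAZINE_FORMULA = "C8H14ClN5"  # default nitrogen-normalization reference
BASELINE_ID = "none"           # supplement id of the no-supplement run

#: Standard stimulant dose and default target-compound dose, mmol/gDW.
STANDARD_DOSE = 50.0


@dataclass(frozen=True)
class SupplementSpec:
    """One screening candidate. ``excluded`` flags nonpractical additives
    (dipeptides, toxics, ...) that are listed but never simulated."""

    id: str
    name: str = ""
    formula: str = ""
    excluded: bool = False


def normalized_dose(
    supplement_formula: str,
    reference_formula: str,
    reference_dose: float,
    element: str,
    exact: bool = False,
) -> float:
    """Dose delivering the same molar amount of ``element`` as the reference.

    Doses are floored to integer mmol by default (matching how dose tables
    are printed); ``exact=True`` returns the unrounded ratio.
    """
    n_sup = element_count(supplement_formula, element)
    n_ref = element_count(reference_formula, element)
    if n_sup == 0:
        raise ValueError(
            f"supplement formula {supplement_formula!r} contains no {element}: "
            f"not a {element} source"
        )
    if n_ref == 0:
        raise ValueError(
            f"reference formula {reference_formula!r} contains no {element}"
        )
    dose = reference_dose * n_ref / n_sup
    return dose if exact else float(math.floor(dose))


def carbon_normalized_dose(
    supplement: SupplementSpec | str,
    reference_formula: str = GLUCOSE_FORMULA,
    reference_dose: float = STANDARD_DOSE,
    exact: bool = False,
) -> float:
    formula = supplement.formula if isinstance(supplement, SupplementSpec) else supplement
    return normalized_dose(formula, reference_formula, reference_dose, "C", exact)


def nitrogen_normalized_dose(
    supplement: SupplementSpec | str,
    reference_formula: str = ATRAZINE_FORMULA,
    reference_dose: float = STANDARD_DOSE,
    exact: bool = False,
) -> float:
    formula = supplement.formula if isinstance(supplement, SupplementSpec) else supplement
    return normalized_dose(formula, reference_formula, reference_dose, "N", exact)


def build_medium(
    mmm_ions: tuple[str, ...] | list[str] = MMM_IONS,
    target_dose: tuple[str, float] = ("atz_e", STANDARD_DOSE),
    supplement_dose: tuple[str, float] | None = None,
    known_ids: set[str] | None = None,
) -> MediumState:
    """Minimal mineral medium + finite target dose + optional supplement.

    ``known_ids``, when given, is the union of the models' exchange
    metabolites; ids outside it are rejected. Mineral ions go to the
    unlimited set; only the target and the supplement are finite pools.
    """
    target_id, target_amount = target_dose
    amounts = {target_id: float(target_amount)}
    if supplement_dose is not None:
        supp_id, supp_amount = supplement_dose
        if supp_id == target_id:
            raise ValueError(
                f"supplement id {supp_id!r} equals the degradation target"
            )
        amounts[supp_id] = float(supp_amount)
    if known_ids is not None:
        unknown = set(amounts) - known_ids
        if unknown:
            raise KeyError(f"metabolite ids not in any exchange set: {sorted(unknown)}")
    return MediumState(amounts=amounts, unlimited=set(mmm_ions))


@dataclass
class ScreenResult:
    """Supplement x species x round table plus per-candidate bookkeeping.

    ``table`` columns: supplement, species, round, biomass, growth_flux,
    target_remaining, supplement_remaining, cum_degradation,
    cum_supplement_consumption. Pool-level columns repeat across the
    species rows of a round. Rows run to the configured horizon; after a
    simulation converges its final state is carried forward (growth-only
    dynamics: nothing changes after convergence).
    """

    table: pd.DataFrame
    target_id: str
    mode: str
    doses: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    failed: dict[str, str] = field(default_factory=dict)


def _trajectory_rows(
    supplement_id: str,
    traj: Trajectory,
    target_id: str,
    supp_met: str | None,
    horizon: int,
) -> list[dict]:
    species = sorted(traj.states[0].biomass)
    target0 = traj.states[0].medium.amounts.get(target_id, 0.0)
    supp0 = traj.states[0].medium.amounts.get(supp_met, 0.0) if supp_met else 0.0
    mu = {
        (rec["round"], rec["species"]): rec["growth_flux"] for rec in traj.records
    }
    rows = []
    for rnd in range(1, horizon + 1):
        st = traj.states[min(rnd, traj.n_rounds)]
        t_rem = st.medium.amounts.get(target_id, 0.0)
        s_rem = st.medium.amounts.get(supp_met, 0.0) if supp_met else 0.0
        for sp in species:
            rows.append(
                {
                    "supplement": supplement_id,
                    "species": sp,
                    "round": rnd,
                    "biomass": st.biomass[sp],
                    "growth_flux": mu.get((rnd, sp), 0.0),
                    "target_remaining": t_rem,
                    "supplement_remaining": s_rem,
                    "cum_degradation": target0 - t_rem,
                    "cum_supplement_consumption": supp0 - s_rem,
                }
            )
    return rows


def screen_supplements(
    models: list[MetabolicModel],
    candidates: list[SupplementSpec],
    mode: str = "molar",
    config: SimConfig | None = None,
    target_dose: tuple[str, float] | None = None,
    reference_formula: str | None = None,
    reference_dose: float = STANDARD_DOSE,
    mmm_ions: tuple[str, ...] = MMM_IONS,
) -> ScreenResult:
    """Run the supplement x species grid: one simulation per candidate plus
    a no-supplement baseline.

    ``mode`` is "molar" (every candidate at ``reference_dose``), "carbon"
    or "nitrogen" (element-normalized against ``reference_formula``,
    defaulting to glucose / the target compound). Candidates flagged
    excluded, lacking the normalization element, or whose simulation fails
    are recorded in ``skipped`` / ``failed`` — a grid run always completes.
    """
    if mode not in ("molar", "carbon", "nitrogen"):
        raise ValueError(f"unknown mode {mode!r}")
    if config is None:
        config = SimConfig()
    if target_dose is None:
        targets = {m.degradation_target for m in models if m.degradation_target}
        if len(targets) != 1:
            raise ValueError(
                f"cannot infer a unique degradation target from models: {targets}"
            )
        target_dose = (targets.pop(), STANDARD_DOSE)
    if reference_formula is None:
        reference_formula = GLUCOSE_FORMULA if mode == "carbon" else ATRAZINE_FORMULA

    horizon = config.max_rounds
    rows: list[dict] = []
    doses: dict[str, float] = {}
    skipped: dict[str, str] = {}
    failed: dict[str, str] = {}

    baseline_medium = build_medium(mmm_ions, target_dose, None)
    baseline = simulate(models, baseline_medium, config)
    rows.extend(_trajectory_rows(BASELINE_ID, baseline, target_dose[0], None, horizon))

    for cand in sorted(candidates, key=lambda c: c.id):
        if cand.excluded:
            skipped[cand.id] = "excluded (nonpractical additive)"
            continue
        try:
            if mode == "molar":
                dose = reference_dose
            elif mode == "carbon":
                dose = carbon_normalized_dose(cand, reference_formula, reference_dose)
            else:
                dose = nitrogen_normalized_dose(cand, reference_formula, reference_dose)
        except ValueError as exc:
            skipped[cand.id] = str(exc)
            log.info("skipping %s: %s", cand.id, exc)
            continue
        medium = build_medium(mmm_ions, target_dose, (cand.id, dose))
        try:
            traj = simulate(models, medium, config)
        except RuntimeError as exc:  # pragma: no cover - defensive
            failed[cand.id] = str(exc)
            log.warning("simulation failed for %s: %s", cand.id, exc)
            continue
        doses[cand.id] = dose
        rows.extend(_trajectory_rows(cand.id, traj, target_dose[0], cand.id, horizon))

    table = pd.DataFrame(rows).sort_values(
        ["supplement", "round", "species"], kind="stable"
    ).reset_index(drop=True)
    return ScreenResult(
        table=table, target_id=target_dose[0], mode=mode,
        doses=doses, skipped=skipped, failed=failed,
    )


def rank_supplements(
    result: ScreenResult,
    criterion: str = "final_degradation",
    round_index: int | None = None,
) -> pd.DataFrame:
    """Rank supplements by community degradation or total biomass at a round.

    Descending stable sort, ties broken lexicographically by supplement id.
    The no-supplement baseline is reported in the ``baseline`` attribute of
    the returned frame, not ranked.
    """
    if criterion not in ("final_degradation", "final_biomass"):
        raise ValueError(f"unknown criterion {criterion!r}")
    tab = result.table
    if tab.empty:
        raise ValueError("empty screen result")
    if round_index is None:
        round_index = int(tab["round"].max())
    at = tab[tab["round"] == round_index]
    if at.empty:
        raise ValueError(f"round {round_index} not present in screen result")

    def _score(group: pd.DataFrame) -> float:
        if criterion == "final_degradation":
            return float(group["cum_degradation"].iloc[0])  # pool-level, repeated
        return float(group["biomass"].sum())

    scores = {
        supp: _score(g) for supp, g in at.groupby("supplement") if supp != BASELINE_ID
    }
    ranking = pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["supplement", "score"],
    )
    base = at[at["supplement"] == BASELINE_ID]
    ranking.attrs["baseline"] = _score(base) if not base.empty else math.nan
    ranking.attrs["criterion"] = criterion
    ranking.attrs["round"] = round_index
    return ranking


def read_supplements(path: str | Path) -> list[SupplementSpec]:
    """Candidate list TSV: columns id, name, formula, excluded (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "name": str})
    specs = []
    for _, row in df.iterrows():
        formula = row.get("formula", "")
        specs.append(
            SupplementSpec(
                id=row["id"],
                name=str(row.get("name", "") or ""),
                formula="" if pd.isna(formula) else str(formula),
                excluded=bool(int(row.get("excluded", 0) or 0)),
            )
        )
    return specs


def write_supplements(specs: list[SupplementSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": s.id, "name": s.name, "formula": s.formula,
             "excluded": int(s.excluded)}
            for s in specs
        ]
    ).to_csv(path, sep="\t", index=False)
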