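"""Run configuration, report writing and the end-to-end pipeline.

A :class:`RunConfig` captures everything a screen-and-validate run needs;
its canonical JSON serialization is hashed (sha256, first 12 hex digits)
and stamped into every output file, so two runs with equal hashes are
byte-identical and any report can be traced back to its exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dfba import MMM_IONS, SimConfig, Trajectory
from .io import load_model
from .screening import (
    ScreenResult,
    rank_supplements,
    read_supplements,
    screen_supplements,
)
from .validation import (
    DEFAULT_EVALUATION_ROUND,
    DEFAULT_FOLD_THRESHOLD,
    classify_predictions,
    fold_change_matrix,
    read_observation_table,
    score,
)

__all__ = ["RunConfig", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)

_TRAJECTORY_COLUMNS = [
    "round", "species", "biomass", "growth_flux",
    "target_remaining", "supplement_remaining",
]
_SCREEN_COLUMNS = [
    "supplement", "species", "round", "biomass", "growth_flux",
    "target_remaining", "supplement_remaining",
    "cum_degradation", "cum_supplement_consumption",
]


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; YAML-serializable."""

    model_paths: list[str]
    candidates_path: str | None = None
    observations_path: str | None = None
    mode: str = "molar"
    target_id: str | None = None        # None: inferred from the models
    target_dose: float = 50.0
    mmm_ions: list[str] = field(default_factory=lambda: list(MMM_IONS))
    vmax: float = 1.0
    max_rounds: int = 15
    convergence_tol: float = 1e-6
    initial_biomass: float = 1.0
    biomass_update: str = "multiplicative"
    tie_break: str = "pfba"
    evaluation_round: int = DEFAULT_EVALUATION_ROUND
    threshold: float = DEFAULT_FOLD_THRESHOLD
    out_dir: str = "."
    seed: int = 0

    def sim_config(self) -> SimConfig:
        return SimConfig(
            vmax=self.vmax,
            max_rounds=self.max_rounds,
            convergence_tol=self.convergence_tol,
            initial_biomass=self.initial_biomass,
            biomass_update=self.biomass_update,
            tie_break=self.tie_break,
        )

    def config_hash(self) -> str:
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_stamped_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Screen -> rank -> fold-change matrix -> (optional) confusion scoring.

    Writes screen.tsv, ranking.tsv, predictions.tsv, confusion.json (when
    observations are given), the resolved config and a log file into
    ``config.out_dir``; returns the report bundle as a dict. Fails fast on
    a missing observation table, before any simulation starts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    obs = None
    if config.observations_path is not None:
        obs = read_observation_table(config.observations_path)  # fail early

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("biostim")
    root.addHandler(handler)
    try:
        log.info("run config hash %s", chash)
        models = [load_model(p) for p in config.model_paths]
        if config.candidates_path is None:
            raise ValueError("candidates_path is required for a pipeline run")
        candidates = read_supplements(config.candidates_path)

        target_dose = None
        if config.target_id is not None:
            target_dose = (config.target_id, config.target_dose)
        result = screen_supplements(
            models,
            candidates,
            mode=config.mode,
            config=config.sim_config(),
            target_dose=target_dose,
            mmm_ions=tuple(config.mmm_ions),
        )
        ranking = rank_supplements(result)
        fc = fold_change_matrix(result, config.evaluation_round)
        calls = classify_predictions(fc, config.threshold)

        config.to_yaml(out / "config.yaml")
        _write_stamped_tsv(result.table[_SCREEN_COLUMNS], out / "screen.tsv", chash)
        _write_stamped_tsv(ranking, out / "ranking.tsv", chash)
        fc_long = fc.reset_index().melt(
            id_vars="supplement", var_name="species", value_name="fold_change"
        )
        fc_long["positive"] = calls.reset_index().melt(id_vars="supplement")[
            "value"
        ].astype(int)
        _write_stamped_tsv(fc_long, out / "predictions.tsv", chash)

        bundle = {
            "config_hash": chash,
            "screen": result,
            "ranking": ranking,
            "fold_changes": fc,
            "calls": calls,
        }
        if obs is not None:
            summary = score(calls, obs)
            report = {"config_hash": chash, **summary.as_dict()}
            with open(out / "confusion.json", "w") as fh:
                json.dump(report, fh, indent=1)
                fh.write("\n")
            bundle["confusion"] = summary
            log.info(
                "confusion: TP=%d TN=%d FP=%d FN=%d accuracy=%.4f",
                summary.tp, summary.tn, summary.fp, summary.fn, summary.accuracy,
            )
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()


def summarize(
    obj: Trajectory | ScreenResult,
    path: str | Path,
    format: str | None = None,
    target_id: str | None = None,
    supplement_id: str | None = None,
) -> None:
    """Export a trajectory or screen result as TSV or JSON (fixed column
    order, lossless for all recorded fields)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")

    if isinstance(obj, Trajectory):
        rows = []
        for rec in obj.records:
            st = obj.states[rec["round"]]
            rows.append(
                {
                    "round": rec["round"],
                    "species": rec["species"],
                    "biomass": rec["biomass"],
                    "growth_flux": rec["growth_flux"],
                    "target_remaining": st.medium.amounts.get(target_id, 0.0)
                    if target_id
                    else 0.0,
                    "supplement_remaining": st.medium.amounts.get(supplement_id, 0.0)
                    if supplement_id
                    else 0.0,
                }
            )
        df = pd.DataFrame(rows, columns=_TRAJECTORY_COLUMNS)
    elif isinstance(obj, ScreenResult):
        df = obj.table.reindex(columns=_SCREEN_COLUMNS)
    else:
        raise TypeError(f"cannot summarize {type(obj).__name__}")

    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
            fh.write("\n")
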