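"""Prediction matrix, binary calls and confusion scoring.

The screen's per-species growth responses are condensed into a supplement x
species fold-change matrix at one evaluation round (default round 3): the
biomass under each supplement divided by the no-supplement baseline biomass
of the same species at the same round. A cell is called a positive
prediction when growth at least doubles (fold change >= 2). Crossing the
calls with an observation table of significant abundance increases yields
TP/TN/FP/FN counts, accuracy (TP+TN)/total and precision TP/(TP+FP).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .screening import BASELINE_ID, ScreenResult

__all__ = [
    "ConfusionSummary",
    "fold_change_matrix",
    "classify_predictions",
    "score",
    "read_observation_table",
    "write_observation_table",
    "DEFAULT_EVALUATION_ROUND",
    "DEFAULT_FOLD_THRESHOLD",
]

DEFAULT_EVALUATION_ROUND = 3
DEFAULT_FOLD_THRESHOLD = 2.0


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        """TP/(TP+FP); NaN (with a warning) when nothing was called positive."""
        if self.tp + self.fp == 0:
            warnings.warn(
                "no positive predictions: precision is undefined (NaN)",
                RuntimeWarning,
                stacklevel=2,
            )
            return math.nan
        return self.tp / (self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "accuracy": self.accuracy,
            "precision": self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan,
        }


def fold_change_matrix(
    screen: ScreenResult | pd.DataFrame,
    round_index: int = DEFAULT_EVALUATION_ROUND,
) -> pd.DataFrame:
    """Supplement x species fold changes versus the no-supplement baseline.

    Degenerate baselines are handled by convention: baseline biomass 0 with
    positive supplemented biomass maps to +inf (unambiguous support), and
    0/0 maps to 1.0 (no change). The returned frame records the evaluation
    round in ``attrs["round"]``.
    """
    table = screen.table if isinstance(screen, ScreenResult) else screen
    at = table[table["round"] == round_index]
    if at.empty:
        raise ValueError(f"round {round_index} not present in screen result")
    base = at[at["supplement"] == BASELINE_ID].set_index("species")["biomass"]
    if base.empty:
        raise ValueError("no-supplement baseline missing from screen result")

    def _fc(row) -> float:
        b = base.get(row["species"])
        if b is None:
            raise ValueError(f"species {row['species']!r} missing from baseline")
        if b == 0:
            return math.inf if row["biomass"] > 0 else 1.0
        return row["biomass"] / b

    supplemented = at[at["supplement"] != BASELINE_ID].copy()
    supplemented["fold_change"] = supplemented.apply(_fc, axis=1)
    matrix = supplemented.pivot(
        index="supplement", columns="species", values="fold_change"
    ).sort_index(axis=0).sort_index(axis=1)
    matrix.attrs["round"] = round_index
    return matrix


def classify_predictions(
    matrix: pd.DataFrame, threshold: float = DEFAULT_FOLD_THRESHOLD
) -> pd.DataFrame:
    """Positive call iff fold change >= threshold ("at least" is inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    calls = matrix >= threshold
    calls.attrs.update(matrix.attrs)
    calls.attrs["threshold"] = threshold
    return calls


def score(pred: pd.DataFrame, obs: pd.DataFrame) -> ConfusionSummary:
    """Cross boolean prediction and observation matrices cell by cell.

    Both frames must cover identical supplement/species index sets; a
    mismatch raises with the missing cells listed.
    """
    missing_rows = set(pred.index).symmetric_difference(obs.index)
    missing_cols = set(pred.columns).symmetric_difference(obs.columns)
    if missing_rows or missing_cols:
        raise ValueError(
            "prediction/observation index mismatch: "
            f"supplements {sorted(missing_rows)}, species {sorted(missing_cols)}"
        )
    p = pred.sort_index(axis=0).sort_index(axis=1).astype(bool)
    o = obs.loc[p.index, p.columns].astype(bool)
    tp = int((p & o).values.sum())
    tn = int((~p & ~o).values.sum())
    fp = int((p & ~o).values.sum())
    fn = int((~p & o).values.sum())
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn)


def read_observation_table(path: str | Path) -> pd.DataFrame:
    """Long-format TSV (supplement, species, increased: 0/1) -> boolean matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    matrix = (
        df.pivot(index="supplement", columns="species", values="increased")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    if matrix.isna().any().any():
        cells = [
            (s, sp)
            for s in matrix.index
            for sp in matrix.columns
            if pd.isna(matrix.at[s, sp])
        ]
        raise ValueError(f"observation table has missing cells: {cells}")
    return matrix.astype(bool)


def write_observation_table(matrix: pd.DataFrame, path: str | Path) -> None:
    long = matrix.astype(int).reset_index().melt(
        id_vars="supplement", var_name="species", value_name="increased"
    )
    long.sort_values(["supplement", "species"]).to_csv(path, sep="\t", index=False)
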