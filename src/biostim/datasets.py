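"""Accessors for the small tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import SupplementSpec, read_supplements
from .validation import read_observation_table

__all__ = [
    "soil_observations",
    "published_fold_changes",
    "named_supplements",
]


def _data_path(name: str):
    return resources.files("biostim").joinpath("data", name)


def soil_observations() -> pd.DataFrame:
    """Boolean supplement x genus matrix of significant abundance increases
    observed in supplemented, herbicide-treated soil (four degrader genera,
    six supplements)."""
    with resources.as_file(_data_path("soil_observations.tsv")) as p:
        return read_observation_table(p)


def published_fold_changes() -> pd.DataFrame:
    """Synthetic stand-in for the deposited community-simulation fold-change
    matrix (see the file header); its >= 2-fold classification matches the
    published binary calls."""
    with resources.as_file(_data_path("community_foldchanges_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return (
        df.pivot(index="supplement", columns="species", values="fold_change")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )


def named_supplements() -> list[SupplementSpec]:
    """The six named screening supplements with chemical formulas."""
    with resources.as_file(_data_path("supplements.tsv")) as p:
        return read_supplements(p)
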