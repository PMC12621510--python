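"""Reduction / expansion strategies for dependent effect sizes.

Each strategy turns a long-format :class:`~masemdep.simulate.MetaDataset`
(possibly several records per Y-cell within a study) into the wide per-study
input of Stage-1 pooling, with at most one value per (study, cell):

* ``simple_average`` -- arithmetic mean of the dependent records per cell;
* ``weighted_average`` -- inverse-sampling-variance weighted mean, with
  v = (1 - r^2)^2 / (n - 1);
* ``random_select`` -- one record per cell chosen uniformly at random;
* ``largest_select`` -- the record with the largest signed value (ties broken
  by lowest effect id);
* ``ignore`` -- every row of the within-study effect table becomes a
  pseudo-study of its own, as if the dependent records came from independent
  studies; the non-Y cells appear only in the first pseudo-study.

The three-level WPL model consumes the unreduced dataset and lives in
:mod:`masemdep.wpl`.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population_model import CELLS
from .simulate import MetaDataset, NON_Y_CELLS

STRATEGIES = (
    "simple_average",
    "weighted_average",
    "random_select",
    "largest_select",
    "ignore",
)

#: all strategy labels accepted by the runner, incl. the modeling approach
ALL_STRATEGIES = STRATEGIES + ("wpl",)


def sampling_variance(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Large-sample variance of a Pearson correlation, (1 - r^2)^2 / (n - 1)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    return (1.0 - r**2) ** 2 / (n - 1.0)


@dataclass
class ReducedDataset:
    """Wide per-study table: one row per (pseudo-)study, one column per cell
    (NaN where unobserved), plus ``study``, ``n`` and -- for pseudo-studies
    created by the ignore strategy -- the ``parent`` study id."""

    table: pd.DataFrame
    strategy: str

    def to_csv(self, path: str | Path) -> None:
        long = self.table.melt(
            id_vars=[c for c in ("study", "parent", "n") if c in self.table],
            value_vars=list(CELLS),
            var_name="cell",
            value_name="r",
        ).dropna(subset=["r"])
        long.to_csv(path, index=False)


def _pivot(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.pivot(index="study", columns="cell", values="r")
    wide = wide.reindex(columns=list(CELLS))
    n = df.drop_duplicates("study").set_index("study")["n"]
    wide.insert(0, "n", n)
    return wide.reset_index()


def _aggregate(df: pd.DataFrame, weighted: bool) -> pd.DataFrame:
    if weighted:
        w = 1.0 / sampling_variance(df["r"].to_numpy(), df["n"].to_numpy())
        df = df.assign(_w=w, _wr=w * df["r"].to_numpy())
        g = df.groupby(["study", "cell"], sort=False)
        pooled = (g["_wr"].sum() / g["_w"].sum()).rename("r").reset_index()
    else:
        pooled = df.groupby(["study", "cell"], sort=False)["r"].mean().reset_index()
    pooled = pooled.merge(df.drop_duplicates("study")[["study", "n"]], on="study")
    return pooled


def _select(df: pd.DataFrame, rng: np.random.Generator | None, largest: bool) -> pd.DataFrame:
    if largest:
        # signed maximum; ties broken by lowest effect id
        df = df.sort_values(["study", "cell", "r", "effect"],
                            ascending=[True, True, False, True], kind="stable")
    else:
        if rng is None:
            raise ValueError("random_select requires an rng")
        df = df.assign(_key=rng.random(len(df)))
        df = df.sort_values(["study", "cell", "_key"], kind="stable")
    return df.groupby(["study", "cell"], sort=False).head(1)


def _ignore(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["study", "cell", "effect"], kind="stable")
    cell_codes = {c: i for i, c in enumerate(CELLS)}
    cell = df["cell"].map(cell_codes).to_numpy()
    study = df["study"].to_numpy()
    r = df["r"].to_numpy(dtype=float)
    n = df["n"].to_numpy()

    # position of each record within its (study, cell) group
    key_new = np.r_[True, (study[1:] != study[:-1]) | (cell[1:] != cell[:-1])]
    first = np.maximum.accumulate(np.where(key_new, np.arange(len(df)), 0))
    pos = np.arange(len(df)) - first
    is_non_y = np.isin(cell, [cell_codes[c] for c in NON_Y_CELLS])
    row = np.where(is_non_y, 0, pos)

    parents, study_inv = np.unique(study, return_inverse=True)
    depth = np.zeros(len(parents), dtype=int)
    np.maximum.at(depth, study_inv, row + 1)
    offsets = np.concatenate([[0], np.cumsum(depth)])

    values = np.full((offsets[-1], len(CELLS)), np.nan)
    values[offsets[study_inv] + row, cell] = r
    n_study = np.zeros(len(parents), dtype=int)
    n_study[study_inv] = n

    wide = pd.DataFrame(values, columns=list(CELLS))
    wide.insert(0, "study", np.arange(offsets[-1]))
    wide.insert(1, "parent", np.repeat(parents, depth))
    wide.insert(2, "n", np.repeat(n_study, depth))
    return wide


def apply_strategy(
    data: MetaDataset,
    strategy: str,
    rng: np.random.Generator | None = None,
) -> ReducedDataset:
    """Reduce a dataset with dependent effect sizes to one value per
    (study, cell) under the given strategy (see module docstring)."""
    df = data.records
    if df.empty:
        raise ValueError("dataset has no records")
    if strategy == "simple_average":
        table = _pivot(_aggregate(df, weighted=False))
    elif strategy == "weighted_average":
        table = _pivot(_aggregate(df, weighted=True))
    elif strategy == "random_select":
        table = _pivot(_select(df, rng, largest=False))
    elif strategy == "largest_select":
        table = _pivot(_select(df, None, largest=True))
    elif strategy == "ignore":
        table = _ignore(df)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ReducedDataset(table=table, strategy=strategy)
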