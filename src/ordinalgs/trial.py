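"""Ordinal multi-environment trial records.

The unit of observation is a *cell*: one line scored for one trait in one
environment, with an ordered categorical outcome coded 1..C.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["OrdinalTrialTable"]

REQUIRED_COLUMNS = ("env_id", "line_id", "trait", "category")


class OrdinalTrialTable:
    """Table of (environment, line, trait, ordinal category) records.

    Categories are stored densely recoded to consecutive integers 1..C per
    trait; the original labels are retained in :attr:`category_maps`.

    Parameters
    ----------
    df : DataFrame
        Columns ``env_id, line_id, trait, category``; one row per cell.
    recode : bool
        Densify category codes per trait (default True).
    """

    def __init__(self, df: pd.DataFrame, recode: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["env_id"] = df["env_id"].astype(str)
        df["line_id"] = df["line_id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        cat = df["category"]
        as_float = pd.to_numeric(cat, errors="coerce")
        bad = as_float.isna() | (as_float != np.round(as_float))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-integer category {cat.iloc[row]!r} at row {row}"
            )
        df["category"] = as_float.astype(int)

        dup = df.duplicated(subset=["env_id", "line_id", "trait"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            rec = df.iloc[row]
            raise ValueError(
                f"duplicate cell (env={rec.env_id}, line={rec.line_id}, "
                f"trait={rec.trait}) at row {row}"
            )

        self.category_maps: dict[str, dict[int, int]] = {}
        if recode:
            for trait, sub in df.groupby("trait", sort=True):
                labels = sorted(sub["category"].unique())
                mapping = {lab: k + 1 for k, lab in enumerate(labels)}
                self.category_maps[trait] = mapping
                sel = df["trait"] == trait
                df.loc[sel, "category"] = df.loc[sel, "category"].map(mapping)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique())

    @property
    def env_ids(self) -> list:
        return sorted(self.df["env_id"].unique())

    @property
    def line_ids(self) -> list:
        return sorted(self.df["line_id"].unique())

    def n_categories(self, trait: str) -> int:
        return int(self.df.loc[self.df["trait"] == trait, "category"].max())

    def subset(self, trait: str | None = None, rows=None) -> "OrdinalTrialTable":
        df = self.df
        if trait is not None:
            df = df[df["trait"] == trait]
        if rows is not None:
            df = df.loc[rows]
        out = OrdinalTrialTable(df.copy(), recode=False)
        out.category_maps = self.category_maps
        return out

    def cell_indices(self, env_order, line_order) -> tuple[np.ndarray, np.ndarray]:
        """(environment, line) integer indices of each row under given orders."""
        env_pos = {e: i for i, e in enumerate(env_order)}
        line_pos = {l: j for j, l in enumerate(line_order)}
        unknown_env = set(self.df["env_id"]) - set(env_pos)
        if unknown_env:
            raise KeyError(f"unknown environment id(s): {sorted(unknown_env)}")
        unknown_line = set(self.df["line_id"]) - set(line_pos)
        if unknown_line:
            raise KeyError(f"unknown line id(s): {sorted(unknown_line)}")
        i = self.df["env_id"].map(env_pos).to_numpy()
        j = self.df["line_id"].map(line_pos).to_numpy()
        return i, j
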