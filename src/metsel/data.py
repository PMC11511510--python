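"""Plot-level trial data container.

A :class:`TrialData` holds one trait observation per plot in long format with
the design factors of a randomized complete block trial repeated over years:
``accession`` (genotype), ``year``, ``block`` (replicate within year),
``column`` (sub-block position, nested in year x block) and the ``trait`` /
``value`` pair.  It is the single currency passed between the generator, the
mixed-model fits and the selection stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG_COLUMNS = ["accession", "year", "block", "column", "trait", "value"]
KEY_COLUMNS = ["accession", "year", "block", "trait"]


class TrialDataError(ValueError):
    """Raised for malformed plot-level data (missing columns, duplicate plots)."""


def _ordered_unique(values) -> list:
    """Unique values in order of first appearance."""
    return list(pd.unique(pd.Series(values)))


@dataclass
class TrialData:
    """Long-format plot observations with design factors.

    Parameters
    ----------
    long
        DataFrame with columns ``accession, year, block, column, trait, value``.
        Factor level order is preserved as order of first appearance.
    """

    long: pd.DataFrame
    accessions: list = field(init=False)
    years: list = field(init=False)
    blocks: list = field(init=False)
    traits: list = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.long.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        df = self.long.loc[:, LONG_COLUMNS].reset_index(drop=True)
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = df.index[values.isna() & df["value"].notna()]
        if len(bad):
            raise TrialDataError(
                f"non-numeric trait values at rows {list(bad[:5])} "
                f"(e.g. {df.loc[bad[0], 'value']!r})"
            )
        df["value"] = values.astype(float)
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            first = df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise TrialDataError(
                f"duplicate plot rows for key {first} "
                f"({int(dup.sum())} rows involved)"
            )
        self.long = df
        self.accessions = _ordered_unique(df["accession"])
        self.years = _ordered_unique(df["year"])
        self.blocks = _ordered_unique(df["block"])
        self.traits = _ordered_unique(df["trait"])

    # ------------------------------------------------------------------ views
    def trait_frame(self, trait: str, dropna: bool = True) -> pd.DataFrame:
        """Rows of one trait, with the ``value`` column; optionally drop NaN."""
        if trait not in self.traits:
            raise KeyError(f"trait {trait!r} not in dataset (has {self.traits})")
        df = self.long[self.long["trait"] == trait]
        if dropna:
            df = df.dropna(subset=["value"])
        return df.reset_index(drop=True)

    def to_wide(self) -> pd.DataFrame:
        """One row per plot, one column per trait."""
        wide = self.long.pivot_table(
            index=["accession", "year", "block", "column"],
            columns="trait",
            values="value",
            aggfunc="first",
            sort=False,
        ).reset_index()
        wide.columns.name = None
        # preserve trait column order
        return wide[["accession", "year", "block", "column", *self.traits]]

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "TrialData":
        """Build from one-row-per-plot layout (trait columns after the factors)."""
        id_cols = ["accession", "year", "block", "column"]
        missing = [c for c in id_cols if c not in wide.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        trait_cols = [c for c in wide.columns if c not in id_cols]
        if not trait_cols:
            raise TrialDataError("wide table has no trait columns")
        long = wide.melt(
            id_vars=id_cols, value_vars=trait_cols, var_name="trait", value_name="value"
        )
        # keep plot-major ordering grouped by trait, as the generator writes it
        long["_trait_order"] = long["trait"].map({t: i for i, t in enumerate(trait_cols)})
        long = long.sort_values(["_trait_order"], kind="stable").drop(columns="_trait_order")
        return cls(long.reset_index(drop=True))

    def cell_means(self, trait: str) -> pd.DataFrame:
        """Arithmetic accession x year means of one trait (NaN-aware)."""
        df = self.trait_frame(trait)
        out = (
            df.groupby(["accession", "year"], sort=False)["value"]
            .mean()
            .reset_index()
        )
        return out

    def accession_means(self, trait: str, year) -> pd.Series:
        """Per-accession means of one trait within one year, in level order."""
        df = self.trait_frame(trait)
        df = df[df["year"] == year]
        means = df.groupby("accession", sort=False)["value"].mean()
        return means.reindex(self.accessions)

    def __len__(self) -> int:
        return len(self.long)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialData):
            return NotImplemented
        if self.long.shape != other.long.shape:
            return False
        a = self.long.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)
        b = other.long.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True
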