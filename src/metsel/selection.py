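"""Heritability-weighted phenotypic selection index and final selection.

The index of genotype i in year j is

    I_ij = sum_m h2_m * z_ijm,

where z_ijm is genotype i's adjusted mean for trait m in year j, standardized
across genotypes within that year (mean 0, SD 1, n-1 denominator) and
sign-flipped for traits where smaller raw values are desirable, so that a
larger index is always better.  Heritability weights give the more repeatable
traits the larger say.  One two-year h2 per trait weights both years
identically.

The index is then treated as an additional trait: a plot-level version is
built by applying the same per-year standardization (an affine map) to plot
values, so its genotype x year cell means equal the index computed from
adjusted means, and the fixed-effects model, grand-mean contrasts and year
(stability) contrasts apply to it unchanged.

The final selection scores genotypes on the number of index traits with a
significant favorable grand-mean difference, requiring cross-year consistency
(no significant unfavorable GMD for a counted trait in either year), and
prefers year-stable genotypes among ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialData
from .inference import ContrastResult
from .simulate import TraitSpec

__all__ = [
    "StandardizedTraits",
    "IndexTable",
    "SelectionReport",
    "standardize_orient",
    "selection_index",
    "plot_level_index",
    "index_stability",
    "select_accessions",
]


@dataclass
class StandardizedTraits:
    """Standardized, direction-oriented adjusted means.

    ``table`` has one row per accession x year x trait with columns
    ``mean`` (adjusted mean), ``z`` (within-year standardized) and
    ``oriented`` (sign-flipped so larger is better).  ``centers`` and
    ``scales`` record the per year x trait standardization for reuse on
    plot-level values.
    """

    table: pd.DataFrame
    centers: pd.Series  # (year, trait) -> center
    scales: pd.Series  # (year, trait) -> scale (SD, n-1)
    signs: dict[str, float]  # trait -> +-1


def standardize_orient(
    means: pd.DataFrame,
    specs: dict[str, TraitSpec],
) -> StandardizedTraits:
    """Standardize adjusted means within year across accessions and orient.

    ``means`` is long: columns ``accession, year, trait, mean``.  Every trait
    present must have a direction in ``specs``; a trait with zero SD within a
    year is an error (its z-scores would be undefined).
    """
    req = {"accession", "year", "trait", "mean"}
    if not req.issubset(means.columns):
        raise ValueError(f"means must have columns {sorted(req)}")
    traits = list(pd.unique(means["trait"]))
    for t in traits:
        if t not in specs:
            raise ValueError(f"no direction declared for trait {t!r}")
    out = means.copy()
    centers = {}
    scales = {}
    for (year, trait), grp in out.groupby(["year", "trait"], sort=False):
        if len(grp) < 2:
            raise ValueError(
                f"need >= 2 accessions per year to standardize (year {year}, {trait})"
            )
        mu = grp["mean"].mean()
        sd = grp["mean"].std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"trait {trait!r} has zero SD in year {year}")
        centers[(year, trait)] = mu
        scales[(year, trait)] = sd
        out.loc[grp.index, "z"] = (grp["mean"] - mu) / sd
    signs = {t: specs[t].sign for t in traits}
    out["oriented"] = out["z"] * out["trait"].map(signs)
    return StandardizedTraits(
        table=out.reset_index(drop=True),
        centers=pd.Series(centers),
        scales=pd.Series(scales),
        signs=signs,
    )


@dataclass
class IndexTable:
    """Per accession x year selection index and within-year rank (1 = best)."""

    table: pd.DataFrame  # accession, year, index, rank
    weights: dict[str, float]
    index_traits: list[str]

    def year_difference(self) -> pd.DataFrame:
        """|I_year2 - I_year1| per accession (two-year tables only)."""
        wide = self.table.pivot(index="accession", columns="year", values="index")
        if wide.shape[1] != 2:
            raise ValueError("year_difference requires exactly two years")
        y1, y2 = wide.columns
        out = pd.DataFrame(
            {"abs_difference": (wide[y2] - wide[y1]).abs()}, index=wide.index
        )
        return out.reset_index()


def selection_index(
    std: StandardizedTraits,
    h2: dict[str, float],
    index_traits: list[str] | None = None,
) -> IndexTable:
    """Heritability-weighted sum of oriented z-values, ranked within year.

    Ties in the index are broken by accession label order (first label ranks
    higher).  A missing trait value for any accession is an error — no silent
    imputation.
    """
    tab = std.table
    index_traits = list(index_traits or pd.unique(tab["trait"]))
    missing_w = [t for t in index_traits if t not in h2]
    if missing_w:
        raise ValueError(f"no heritability weight for traits {missing_w}")
    sub = tab[tab["trait"].isin(index_traits)]
    counts = sub.groupby(["accession", "year"], sort=False)["trait"].count()
    if (counts != len(index_traits)).any():
        bad = counts[counts != len(index_traits)].index[0]
        raise ValueError(
            f"accession/year {bad} is missing index traits "
            f"(has {int(counts.loc[bad])} of {len(index_traits)})"
        )
    w = {t: float(h2[t]) for t in index_traits}
    sub = sub.assign(contrib=sub["oriented"] * sub["trait"].map(w))
    idx = (
        sub.groupby(["accession", "year"], sort=False)["contrib"]
        .sum()
        .rename("index")
        .reset_index()
    )
    # rank descending within year; ties by accession label order
    order = {a: i for i, a in enumerate(pd.unique(idx["accession"]))}
    idx["_order"] = idx["accession"].map(order)
    idx = idx.sort_values(["year", "index", "_order"], ascending=[True, False, True])
    idx["rank"] = idx.groupby("year", sort=False).cumcount() + 1
    idx = idx.drop(columns="_order").sort_values(["accession", "year"]).reset_index(drop=True)
    return IndexTable(table=idx, weights=w, index_traits=index_traits)


def plot_level_index(
    data: TrialData,
    std: StandardizedTraits,
    weights: dict[str, float],
    index_traits: list[str],
    trait_name: str = "selection_index",
) -> TrialData:
    """Append the index as an additional plot-level trait.

    Plot values are standardized with the same per-year center/scale used for
    the adjusted means, so the cell means of the plot-level index equal the
    index computed from adjusted means; the full single-trait evaluation
    (model fit, contrasts) then applies to the index unchanged.
    """
    frames = []
    for trait in index_traits:
        df = data.trait_frame(trait).copy()
        c = df["year"].map(lambda yv, t=trait: std.centers[(yv, t)])
        s = df["year"].map(lambda yv, t=trait: std.scales[(yv, t)])
        df["contrib"] = weights[trait] * std.signs[trait] * (df["value"] - c) / s
        frames.append(df)
    allc = pd.concat(frames, ignore_index=True)
    idx_vals = (
        allc.groupby(["accession", "year", "block", "column"], sort=False)["contrib"]
        .agg(["sum", "count"])
        .reset_index()
    )
    incomplete = idx_vals["count"] != len(index_traits)
    idx_vals.loc[incomplete, "sum"] = np.nan
    new = idx_vals.rename(columns={"sum": "value"}).drop(columns="count")
    new["trait"] = trait_name
    combined = pd.concat(
        [data.long, new[["accession", "year", "block", "column", "trait", "value"]]],
        ignore_index=True,
    )
    return TrialData(combined)


def index_stability(index: IndexTable, yc: ContrastResult, alpha: float = 0.05) -> pd.DataFrame:
    """Stability flags: adjusted p of the index year contrast >= alpha."""
    flags = yc.table[["label", "estimate", "p_adj"]].rename(columns={"label": "accession"})
    flags["stable"] = flags["p_adj"] >= alpha
    have = set(flags["accession"])
    need = set(index.table["accession"])
    if have != need:
        raise ValueError("year contrasts and index table cover different accessions")
    return flags.reset_index(drop=True)


@dataclass
class SelectionReport:
    """Final selection with per-accession audit trail."""

    table: pd.DataFrame  # full scoring table, best first
    selected: list[str]
    k: int
    criteria: dict[str, str]  # trait -> favorable direction ("+" / "-")


def select_accessions(
    gmd: pd.DataFrame,
    stability: pd.DataFrame,
    index: IndexTable,
    specs: dict[str, TraitSpec],
    k: int = 10,
    alpha: float = 0.05,
) -> SelectionReport:
    """Score and select the k most broadly superior, consistent genotypes.

    ``gmd`` is long with columns ``accession, year, trait, estimate, p_adj``
    (grand-mean differences; the selection index may appear as one of the
    traits).  A trait counts for an accession when its GMD is significant and
    favorable (sign matching the trait's desired direction) in at least one
    year and never significantly unfavorable; the score is the number of
    significant favorable (trait, year) pairs among counted traits.  Ties are
    broken by year stability of the index, then by mean index rank, then by
    accession label.
    """
    accessions = list(pd.unique(index.table["accession"]))
    if k > len(accessions):
        raise ValueError(f"k={k} exceeds the {len(accessions)} accessions available")
    traits = list(pd.unique(gmd["trait"]))
    sign = {}
    for t in traits:
        if t in specs:
            sign[t] = specs[t].sign
        elif t == "selection_index":
            sign[t] = 1.0
        else:
            raise ValueError(f"no direction declared for GMD trait {t!r}")

    g = gmd.copy()
    g["favorable"] = (g["p_adj"] < alpha) & (
        np.sign(g["estimate"]) == g["trait"].map(sign)
    )
    g["unfavorable"] = (g["p_adj"] < alpha) & (
        np.sign(g["estimate"]) == -g["trait"].map(sign)
    )

    stab = stability.set_index("accession")["stable"]
    mean_rank = index.table.groupby("accession", sort=False)["rank"].mean()

    rows = []
    for acc in accessions:
        sub = g[g["accession"] == acc]
        counted = []
        score = 0
        for t in traits:
            st = sub[sub["trait"] == t]
            if st.empty:
                continue
            if st["favorable"].any() and not st["unfavorable"].any():
                counted.append(t)
                score += int(st["favorable"].sum())
        n_traits = len(counted)
        stable = bool(stab.get(acc, False))
        rationale = (
            f"{n_traits} consistently favorable traits ({', '.join(counted) or 'none'}); "
            f"{score} significant favorable GMDs across years; "
            f"{'stable' if stable else 'not stable'} across years; "
            f"mean index rank {mean_rank.get(acc, np.nan):.1f}"
        )
        rows.append(
            {
                "accession": acc,
                "n_favorable_traits": n_traits,
                "n_favorable_tests": score,
                "stable": stable,
                "mean_index_rank": float(mean_rank.get(acc, np.nan)),
                "rationale": rationale,
            }
        )
    tab = pd.DataFrame(rows)
    order = {a: i for i, a in enumerate(accessions)}
    tab["_order"] = tab["accession"].map(order)
    tab = tab.sort_values(
        by=["n_favorable_traits", "n_favorable_tests", "stable", "mean_index_rank", "_order"],
        ascending=[False, False, False, True, True],
        kind="stable",
    ).drop(columns="_order").reset_index(drop=True)
    tab["selected"] = np.arange(len(tab)) < k
    return SelectionReport(
        table=tab,
        selected=list(tab.loc[tab["selected"], "accession"]),
        k=k,
        criteria={t: ("+" if sign[t] > 0 else "-") for t in traits},
    )
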