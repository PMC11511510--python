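"""Multiple contrast tests and per-year correlation analysis.

Two contrast families are used for a two-year replicated trial:

* grand-mean contrasts — each genotype's adjusted mean within a year minus
  the average of all genotype means in that year (the "grand mean
  difference", GMD), one family per year; and
* year contrasts — each genotype's year-2 mean minus its year-1 mean, one
  family over genotypes; a non-significant year contrast marks the genotype
  as stable across years.

Family-wise adjustment is single-step max-|t|: the adjusted p-value of each
hypothesis is the probability that the largest absolute statistic of the
whole family exceeds it under the joint multivariate t distribution of the
family's statistics, estimated by seeded Monte Carlo.  Sidak and Bonferroni
are available as conservative closed-form fallbacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialData
from .mixed import DesignMatrices, FixedFit, MixedModelError, cell_mean_matrix

__all__ = [
    "ContrastResult",
    "grand_mean_contrasts",
    "year_contrasts",
    "adjust_maxt",
    "pearson_ci",
    "significance_stars",
]

ALPHA_LADDER = (0.05, 0.01, 0.001)


def significance_stars(p: float, ladder=ALPHA_LADDER) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    stars = ""
    for alpha in sorted(ladder, reverse=True):
        if p < alpha:
            stars += "*"
    return stars


@dataclass
class ContrastResult:
    """Per-hypothesis estimates and single-step adjusted p-values."""

    family: str
    table: pd.DataFrame  # label, estimate, se, t, df, p_raw, p_adj, stars

    def __post_init__(self):
        t = self.table
        bad = t[(t["p_adj"] + 1e-12 < t["p_raw"])]
        assert bad.empty, "adjusted p must be >= raw p"

    @property
    def labels(self) -> list:
        return list(self.table["label"])


# -------------------------------------------------------------- adjustment
def adjust_maxt(
    t_stats: np.ndarray,
    correlation: np.ndarray,
    df: int,
    mc_draws: int = 100_000,
    seed: int = 0,
    method: str = "mc",
) -> np.ndarray:
    """Single-step adjusted p-values for a family of t statistics.

    ``method="mc"`` samples the joint multivariate t (correlation matrix may
    be singular, as grand-mean contrast families are); ``"sidak"`` and
    ``"bonferroni"`` are closed-form conservative fallbacks.  Adjusted
    p-values are clipped from below at the raw p-values, and a single
    hypothesis returns its raw two-sided p exactly.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    m = t_stats.shape[0]
    if df <= 0:
        raise ValueError("df must be positive")
    p_raw = 2.0 * stats.t.sf(np.abs(t_stats), df)
    if m == 1:
        return p_raw
    if method == "bonferroni":
        return np.clip(p_raw * m, p_raw, 1.0)
    if method == "sidak":
        return np.clip(1.0 - (1.0 - p_raw) ** m, p_raw, 1.0)
    if method != "mc":
        raise ValueError(f"unknown adjustment method {method!r}")

    C = np.asarray(correlation, dtype=float)
    if C.shape != (m, m):
        raise ValueError("correlation matrix shape must match t_stats")
    C = 0.5 * (C + C.T)
    w, U = np.linalg.eigh(C)
    if w.min() < -1e-6:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g}); use method='sidak'"
        )
    A = U * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    maxabs = np.empty(mc_draws)
    chunk = 20_000
    done = 0
    while done < mc_draws:
        b = min(chunk, mc_draws - done)
        Z = rng.standard_normal((b, m)) @ A.T
        s = np.sqrt(rng.chisquare(df, b) / df)
        maxabs[done : done + b] = np.abs(Z).max(axis=1) / s
        done += b
    maxabs.sort()
    # P(max |T| >= |t_i|), with a +1 continuity guard so p > 0
    exceed = maxabs.size - np.searchsorted(maxabs, np.abs(t_stats), side="left")
    p_adj = (exceed + 1.0) / (maxabs.size + 1.0)
    return np.clip(p_adj, p_raw, 1.0)


def _contrast_result(
    family: str,
    labels: list,
    C: np.ndarray,
    fit: FixedFit,
    mc_draws: int,
    seed: int,
    method: str,
) -> ContrastResult:
    est = C @ fit.beta
    cov = C @ fit.cov @ C.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if np.any(se == 0.0):
        raise MixedModelError(f"zero standard error in family {family!r}")
    t = est / se
    corr = cov / np.outer(se, se)
    df = fit.df_resid
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    p_adj = adjust_maxt(t, corr, df, mc_draws=mc_draws, seed=seed, method=method)
    table = pd.DataFrame(
        {
            "label": labels,
            "estimate": est,
            "se": se,
            "t": t,
            "df": df,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "stars": [significance_stars(p) for p in p_adj],
        }
    )
    return ContrastResult(family=family, table=table)


# ---------------------------------------------------------------- families
def grand_mean_contrasts(
    fit: FixedFit,
    dm: DesignMatrices,
    year,
    mc_draws: int = 100_000,
    seed: int = 0,
    method: str = "mc",
) -> ContrastResult:
    """Each genotype's mean minus the average of all genotype means, one year.

    Estimates are on the trait scale and sum to zero across genotypes by
    construction.
    """
    if year not in dm.year_levels:
        raise MixedModelError(f"year {year!r} not in model (has {dm.year_levels})")
    if len(dm.genotype_levels) < 2:
        raise MixedModelError("grand-mean contrasts need >= 2 genotypes")
    L, idx = cell_mean_matrix(dm)
    mask = (idx["year"] == year).to_numpy()
    M = L[mask]
    m = M.shape[0]
    C = (np.eye(m) - np.full((m, m), 1.0 / m)) @ M
    labels = list(idx.loc[mask, "accession"])
    return _contrast_result(
        f"grand-mean {year}", labels, C, fit, mc_draws, seed, method
    )


def year_contrasts(
    fit: FixedFit,
    dm: DesignMatrices,
    mc_draws: int = 100_000,
    seed: int = 0,
    method: str = "mc",
    alpha: float = 0.05,
) -> ContrastResult:
    """Year-2 minus year-1 adjusted mean per genotype, family-wise adjusted.

    The returned table carries a ``stable`` flag: adjusted p >= ``alpha``.
    """
    if len(dm.year_levels) != 2:
        raise MixedModelError("year contrasts require exactly two years")
    y1, y2 = dm.year_levels
    L, idx = cell_mean_matrix(dm)
    rows = []
    labels = []
    for g in dm.genotype_levels:
        r2 = L[((idx["accession"] == g) & (idx["year"] == y2)).to_numpy()][0]
        r1 = L[((idx["accession"] == g) & (idx["year"] == y1)).to_numpy()][0]
        rows.append(r2 - r1)
        labels.append(g)
    C = np.vstack(rows)
    result = _contrast_result(
        f"year {y2}-{y1}", labels, C, fit, mc_draws, seed, method
    )
    result.table["stable"] = result.table["p_adj"] >= alpha
    return result


# -------------------------------------------------------------- correlation
def pearson_ci(
    data: TrialData,
    traits: list[str] | None = None,
    year=None,
    level: str = "accession_mean",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Pairwise Pearson correlations within one year, with Fisher-z CIs.

    ``level="accession_mean"`` correlates per-accession means (once-per-plot
    scores make plot-level correlation noisy); ``level="plot"`` uses raw plot
    values.  Requires at least 4 paired observations per pair.
    """
    traits = traits or data.traits
    if year is None:
        raise ValueError("year must be given (correlations are split by year)")
    series = {}
    for t in traits:
        if level == "accession_mean":
            series[t] = data.accession_means(t, year)
        elif level == "plot":
            df = data.trait_frame(t)
            df = df[df["year"] == year]
            series[t] = df.set_index(["accession", "block"])["value"]
        else:
            raise ValueError(f"unknown level {level!r}")
    z_crit = stats.norm.ppf(0.5 + conf / 2.0)
    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            pair = pd.concat([series[t1], series[t2]], axis=1, keys=[t1, t2]).dropna()
            n = len(pair)
            if n < 4:
                raise ValueError(f"fewer than 4 paired observations for ({t1}, {t2})")
            x, y = pair[t1].to_numpy(), pair[t2].to_numpy()
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                raise ValueError(f"zero variance in pair ({t1}, {t2})")
            r = float(np.corrcoef(x, y)[0, 1])
            r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
            z = np.arctanh(r_c)
            halfw = z_crit / np.sqrt(n - 3)
            rows.append(
                {
                    "trait_1": t1,
                    "trait_2": t2,
                    "year": year,
                    # clipping keeps r inside its own CI at r = +-1 exactly
                    "ci_low": min(float(np.tanh(z - halfw)), r),
                    "r": r,
                    "ci_high": max(float(np.tanh(z + halfw)), r),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(data: TrialData, year, **kwargs) -> pd.DataFrame:
    """Square symmetric correlation matrix for one year."""
    long = pearson_ci(data, year=year, **kwargs)
    traits = data.traits
    M = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in long.iterrows():
        M.loc[row["trait_1"], row["trait_2"]] = row["r"]
        M.loc[row["trait_2"], row["trait_1"]] = row["r"]
    return M
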