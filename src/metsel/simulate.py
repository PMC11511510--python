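"""Synthetic multi-environment trial generator.

Simulates plot-level phenotypes under the additive random-effects model of a
randomized complete block trial repeated over years,

    y_ijkl = mu + g_i + a_j + (ga)_ij + b_k + (ba)_kj + c_l + e_ijkl,

with genotype (g), year (a), genotype x year (ga), block (b), block x year
(ba), column-within-block (c) effects and plot residuals (e).  Each effect is
drawn independently Normal(0, sigma2) from its own deterministic substream of
the master seed, except genotype effects, which are drawn jointly across
traits from a user-supplied genetic correlation matrix so that trait-trait
correlation at the genotype level can be controlled.  Residuals can be
heteroscedastic by year and correlated across years within a genotype x block
cell — the repeated unit of a re-randomized two-year trial.

The default trait panel reproduces the design and variance magnitudes of the
two-year quinoa trial this package models: 48 accessions x 2 years x 3 blocks,
four columns per block, 13 traits (the 12 tabulated ones plus days to
maturity) with published genotype / year / genotype-by-year / residual
variances and a genotype-level correlation structure with the published sign
pattern (earliness traits mutually positive and positively tied to height,
yield positively tied to kernel weight and negatively to mildew and lodging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published
from .data import TrialData

__all__ = [
    "TrialDesign",
    "VarianceSpec",
    "TraitSpec",
    "GeneticCorrelation",
    "generate_trial",
    "summarize_traits",
    "default_design",
    "default_variance_specs",
    "default_trait_specs",
    "default_genetic_correlation",
]


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class TrialDesign:
    """Field layout: genotypes x years x blocks, columns nested in year x block."""

    n_genotypes: int = 48
    n_years: int = 2
    n_blocks: int = 3
    n_columns_per_block: int = 4
    genotype_labels: tuple[str, ...] | None = None
    year_labels: tuple | None = None

    def __post_init__(self):
        for name in ("n_genotypes", "n_years", "n_blocks", "n_columns_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        labels = self.genotype_labels
        if labels is None:
            labels = tuple(f"G{i + 1:02d}" for i in range(self.n_genotypes))
            object.__setattr__(self, "genotype_labels", labels)
        if len(labels) != self.n_genotypes or len(set(labels)) != len(labels):
            raise ValueError("genotype_labels must be unique and match n_genotypes")
        years = self.year_labels
        if years is None:
            years = tuple(2020 + j for j in range(self.n_years))
            object.__setattr__(self, "year_labels", years)
        if len(years) != self.n_years:
            raise ValueError("year_labels must match n_years")

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_years * self.n_blocks


@dataclass(frozen=True)
class VarianceSpec:
    """Generating variance components for one trait (trait units squared).

    ``year_residual_scales`` multiplies the residual SD per year (length
    n_years); ``residual_year_corr`` correlates the two residuals of a
    genotype x block cell across years (two-year designs only).
    """

    mu: float
    sigma2_g: float = 0.0
    sigma2_year: float = 0.0
    sigma2_gxy: float = 0.0
    sigma2_block: float = 0.0
    sigma2_blockxyear: float = 0.0
    sigma2_column: float = 0.0
    sigma2_resid: float = 0.0
    year_residual_scales: tuple[float, ...] | None = None
    residual_year_corr: float = 0.0

    def __post_init__(self):
        for name in (
            "sigma2_g",
            "sigma2_year",
            "sigma2_gxy",
            "sigma2_block",
            "sigma2_blockxyear",
            "sigma2_column",
            "sigma2_resid",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.residual_year_corr <= 1.0:
            raise ValueError("residual_year_corr must lie in [-1, 1]")


@dataclass(frozen=True)
class TraitSpec:
    """Measurement-scale metadata: selection direction, clamp bounds, rounding."""

    name: str
    direction: str = "higher_is_better"  # or "lower_is_better"
    bounds: tuple[float | None, float | None] | None = None
    rounding: float | None = None  # grid size, e.g. 1.0 for integer days

    def __post_init__(self):
        if self.direction not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sign(self) -> float:
        """+1 if larger raw values are desirable, else -1."""
        return 1.0 if self.direction == "higher_is_better" else -1.0

    def apply_scale(self, values: np.ndarray) -> np.ndarray:
        out = np.asarray(values, dtype=float)
        if self.rounding:
            out = np.round(out / self.rounding) * self.rounding
        if self.bounds is not None:
            lo, hi = self.bounds
            out = np.clip(out, lo if lo is not None else -np.inf,
                          hi if hi is not None else np.inf)
        return out


@dataclass(frozen=True)
class GeneticCorrelation:
    """Correlation matrix of genotype effects across traits."""

    traits: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.traits), len(self.traits)):
            raise ValueError("matrix shape must match trait list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("genetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("genetic correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-8:
            raise ValueError(
                f"genetic correlation matrix is not positive semidefinite "
                f"(min eigenvalue {w.min():.3g})"
            )
        object.__setattr__(self, "matrix", m)

    def submatrix(self, traits: list[str]) -> np.ndarray:
        idx = [self.traits.index(t) for t in traits]
        return self.matrix[np.ix_(idx, idx)]


# ------------------------------------------------------------------ defaults
_DIRECTIONS = {
    "dtf": "lower_is_better",
    "dtm": "lower_is_better",
    "emergence": "higher_is_better",
    "homogeneity": "higher_is_better",
    "panicle_length": "higher_is_better",
    "plant_height": "lower_is_better",
    "panicle_density": "higher_is_better",
    "panicle_shape": "higher_is_better",
    "stem_lodging": "lower_is_better",
    "mildew": "lower_is_better",
    "saponin": "lower_is_better",
    "tkw": "higher_is_better",
    "seed_yield": "higher_is_better",
}

_BOUNDS = {
    "emergence": (0.0, 100.0),
    "homogeneity": (0.0, 100.0),
    "stem_lodging": (0.0, 100.0),
    "panicle_density": (1.0, 9.0),
    "panicle_shape": (1.0, 5.0),
    "mildew": (1.0, 5.0),
    "saponin": (0.0, None),
    "tkw": (0.0, None),
    "seed_yield": (0.0, None),
}

# Days to maturity is part of the published correlation analysis but has no
# tabulated variance components; values chosen once as realistic for a panel
# pre-selected to mature within 160 days.
_DTM_SPEC = dict(mu=112.0, sigma2_g=15.0, sigma2_gxy=6.0, sigma2_resid=2.0)

# Genotype-level factor loadings (earliness E, yield potential Y) from which
# the default genetic correlation is built as L L' + diag(1 - ||l||^2); PSD by
# construction, sign pattern matching the published correlation analysis.
_LOADINGS = {
    "dtf": (0.90, 0.25),
    "dtm": (0.92, 0.25),
    "plant_height": (0.70, 0.10),
    "panicle_length": (0.35, 0.10),
    "saponin": (0.45, 0.20),
    "mildew": (-0.60, -0.30),
    "stem_lodging": (-0.10, -0.45),
    "seed_yield": (0.35, 0.75),
    "tkw": (0.10, 0.60),
    "panicle_density": (0.05, 0.45),
    "emergence": (0.00, 0.25),
    "homogeneity": (0.10, 0.15),
    "panicle_shape": (0.00, 0.00),
}


def default_design() -> TrialDesign:
    """The modeled trial: 48 genotypes x 2 years x 3 blocks, 4 columns/block."""
    return TrialDesign()


def default_variance_specs(
    nuisance_fraction: float = 0.10,
) -> dict[str, VarianceSpec]:
    """Per-trait generating variances from the published component table.

    Block, block x year and column variances are not tabulated in the source
    study; each defaults to ``nuisance_fraction`` of the trait's residual
    variance (a small positional nuisance typical of a well-managed trial).
    """
    specs: dict[str, VarianceSpec] = {}
    for trait, (s2g, s2y, s2gy, s2r, _r2, _h2) in published.VARIANCE_COMPONENTS.items():
        mu = published.TRAIT_SUMMARY[trait][2]
        nui = nuisance_fraction * s2r
        specs[trait] = VarianceSpec(
            mu=mu,
            sigma2_g=s2g,
            sigma2_year=s2y,
            sigma2_gxy=s2gy,
            sigma2_block=nui,
            sigma2_blockxyear=nui,
            sigma2_column=nui,
            sigma2_resid=s2r,
        )
    nui = nuisance_fraction * _DTM_SPEC["sigma2_resid"]
    specs["dtm"] = VarianceSpec(
        sigma2_block=nui, sigma2_blockxyear=nui, sigma2_column=nui, **_DTM_SPEC
    )
    return specs


def default_trait_specs() -> dict[str, TraitSpec]:
    """Directions and measurement bounds for the default trait panel."""
    return {
        name: TraitSpec(name=name, direction=direction, bounds=_BOUNDS.get(name))
        for name, direction in _DIRECTIONS.items()
    }


def default_genetic_correlation() -> GeneticCorrelation:
    """Two-factor genetic correlation with the published sign structure."""
    traits = tuple(_LOADINGS)
    L = np.array([_LOADINGS[t] for t in traits])
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return GeneticCorrelation(traits=traits, matrix=corr)


# ----------------------------------------------------------------- generator
def _column_layout(design: TrialDesign, rng: np.random.Generator) -> np.ndarray:
    """Column index (1..C) per (year, block, genotype), randomized per block.

    Genotypes are spread as evenly as possible over the columns of each
    year x block, with a fresh randomized assignment per block (the physical
    trial grouped entries by maturity; a randomized assignment keeps column
    effects estimable apart from genotype in simulation).
    """
    g, j, k, c = (
        design.n_genotypes,
        design.n_years,
        design.n_blocks,
        design.n_columns_per_block,
    )
    base = np.repeat(np.arange(c), int(np.ceil(g / c)))[:g]
    layout = np.empty((j, k, g), dtype=int)
    for jj in range(j):
        for kk in range(k):
            layout[jj, kk] = base[rng.permutation(g)]
    return layout + 1


def generate_trial(
    design: TrialDesign | None = None,
    var_specs: dict[str, VarianceSpec] | None = None,
    trait_specs: dict[str, TraitSpec] | None = None,
    gcorr: GeneticCorrelation | None = "default",
    seed: int = 0,
    missing_rate: float = 0.0,
    genotype_shifts: dict[str, np.ndarray] | None = None,
    apply_scale: bool = True,
) -> TrialData:
    """Simulate one plot-level trial dataset.

    Parameters
    ----------
    design, var_specs, trait_specs
        Field layout, generating variances and measurement-scale metadata;
        all default to the modeled 48 x 2 x 3 quinoa panel.
    gcorr
        Genotype-effect correlation across traits; ``"default"`` uses the
        built-in two-factor structure, ``None`` draws genotype effects
        independently per trait.
    seed
        Master seed; every random draw derives from it, so equal seeds give
        bit-identical datasets.
    missing_rate
        Fraction of plot x trait values set missing at random (tests the
        unbalanced-data paths).
    genotype_shifts
        Optional per-trait array of length ``n_genotypes`` added to the
        genotype effects — used to plant known signal for recovery studies.
    apply_scale
        Apply each trait's rounding grid and clamp bounds after summing
        effects.  Disable to study the unclipped Gaussian model.
    """
    design = design or default_design()
    var_specs = var_specs if var_specs is not None else default_variance_specs()
    trait_specs = trait_specs if trait_specs is not None else default_trait_specs()
    if isinstance(gcorr, str) and gcorr == "default":
        gcorr = default_genetic_correlation()

    traits = list(var_specs)
    if not traits:
        raise ValueError("var_specs must define at least one trait")
    n_g, n_j, n_k, n_c = (
        design.n_genotypes,
        design.n_years,
        design.n_blocks,
        design.n_columns_per_block,
    )

    master = np.random.SeedSequence(seed)
    ss_layout, ss_geno, ss_missing, *ss_traits = master.spawn(3 + len(traits))
    layout = _column_layout(design, np.random.default_rng(ss_layout))

    # genotype effects, jointly across traits
    sg = np.array([np.sqrt(var_specs[t].sigma2_g) for t in traits])
    z = np.random.default_rng(ss_geno).standard_normal((n_g, len(traits)))
    if gcorr is not None:
        R = gcorr.submatrix(
            [t if t in gcorr.traits else gcorr.traits[0] for t in traits]
        )
        # traits absent from the correlation spec stay independent
        absent = [i for i, t in enumerate(traits) if t not in gcorr.traits]
        for i in absent:
            R[i, :] = 0.0
            R[:, i] = 0.0
            R[i, i] = 1.0
        w, U = np.linalg.eigh(R)
        z = z @ (U * np.sqrt(np.clip(w, 0.0, None))).T
    g_eff = z * sg  # (n_g, n_traits)
    if genotype_shifts:
        for t, shift in genotype_shifts.items():
            if t in traits:
                g_eff[:, traits.index(t)] += np.asarray(shift, dtype=float)

    # plot index arrays (one row per genotype x year x block)
    gi, jj, kk = np.meshgrid(
        np.arange(n_g), np.arange(n_j), np.arange(n_k), indexing="ij"
    )
    gi, jj, kk = gi.ravel(), jj.ravel(), kk.ravel()
    col = layout[jj, kk, gi]

    frames = []
    for ti, trait in enumerate(traits):
        vs = var_specs[trait]
        rng = np.random.default_rng(ss_traits[ti])
        a = rng.normal(0.0, np.sqrt(vs.sigma2_year), n_j)
        ga = rng.normal(0.0, np.sqrt(vs.sigma2_gxy), (n_g, n_j))
        b = rng.normal(0.0, np.sqrt(vs.sigma2_block), n_k)
        ba = rng.normal(0.0, np.sqrt(vs.sigma2_blockxyear), (n_k, n_j))
        c = rng.normal(0.0, np.sqrt(vs.sigma2_column), (n_j, n_k, n_c))

        scales = np.ones(n_j)
        if vs.year_residual_scales is not None:
            scales = np.asarray(vs.year_residual_scales, dtype=float)
            if scales.shape != (n_j,):
                raise ValueError("year_residual_scales must have length n_years")
        sd = np.sqrt(vs.sigma2_resid) * scales
        rho = vs.residual_year_corr
        if rho != 0.0 and n_j == 2:
            # correlated pair per genotype x block cell
            e_pair = rng.standard_normal((n_g, n_k, 2))
            e_pair[..., 1] = rho * e_pair[..., 0] + np.sqrt(1 - rho**2) * e_pair[..., 1]
            e = e_pair * sd  # broadcast over last axis (years)
            e_flat = e[gi, kk, jj]
        else:
            if rho != 0.0:
                raise ValueError(
                    "residual_year_corr is only supported for two-year designs"
                )
            e_flat = rng.standard_normal(gi.shape[0]) * sd[jj]

        y = (
            vs.mu
            + g_eff[gi, ti]
            + a[jj]
            + ga[gi, jj]
            + b[kk]
            + ba[kk, jj]
            + c[jj, kk, col - 1]
            + e_flat
        )
        ts = trait_specs.get(trait)
        if apply_scale and ts is not None:
            y = ts.apply_scale(y)

        frames.append(
            pd.DataFrame(
                {
                    "accession": np.asarray(design.genotype_labels)[gi],
                    "year": np.asarray(design.year_labels)[jj],
                    "block": kk + 1,
                    "column": col,
                    "trait": trait,
                    "value": y,
                }
            )
        )

    long = pd.concat(frames, ignore_index=True)
    if missing_rate > 0.0:
        rng_m = np.random.default_rng(ss_missing)
        mask = rng_m.random(len(long)) < missing_rate
        long.loc[mask, "value"] = np.nan
    return TrialData(long)


# ----------------------------------------------------------------- summaries
def summarize_traits(data: TrialData) -> pd.DataFrame:
    """Per-trait min / max / mean / SD / CV% over all non-missing plots.

    CV% is 100 * SD / mean.  Traits with no non-missing observation are
    excluded with a warning.
    """
    import warnings

    rows = {}
    for trait in data.traits:
        vals = data.trait_frame(trait)["value"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"trait {trait!r} has no non-missing values; excluded")
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows[trait] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "mean": mean,
            "sd": sd,
            "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            "n": int(vals.size),
        }
    if not rows:
        raise ValueError("no trait has any non-missing observation")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trait"
    return out
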