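"""Published reference values from the two-year quinoa field trial.

The source study evaluated 48 quinoa (*Chenopodium quinoa* Willd.) accessions
near Traventhal, northern Germany, in 2020 and 2021 in a randomized complete
block design (three blocks per year, four columns per block).  The raw
plot-level data were not deposited, but the printed summary tables are public
and serve two purposes here:

* they parameterize the synthetic trial generator (trait means, variance
  components, heritability weights), and
* they provide exact round-trip targets for the heritability formula and for
  internal-consistency checks of the selection index.

All values are transcribed verbatim from the publication's tables; nothing in
this module is estimated by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TRAIT_SUMMARY",
    "VARIANCE_COMPONENTS",
    "SELECTION_INDEX_BY_YEAR",
    "INDEX_YEAR_DIFFERENCES",
    "INDEX_TRAITS",
    "trait_summary",
    "variance_components",
    "selection_index_table",
    "index_year_differences",
]

# Trait-level summaries over all plots of both years:
# (minimum, maximum, mean, SD).  The published CV% column is reproduced in
# ``TRAIT_SUMMARY_CV`` for reference but is not 100*SD/mean for any row, so it
# is never asserted or used in computation.
TRAIT_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "dtf": (63.0, 79.0, 69.77, 4.2),
    "emergence": (19.25, 100.0, 48.45, 15.54),
    "homogeneity": (0.0, 100.0, 74.83, 28.52),
    "panicle_length": (10.0, 62.5, 33.37, 7.9),
    "plant_height": (112.5, 217.5, 160.0, 20.56),
    "panicle_density": (1.0, 7.0, 4.71, 1.23),
    "panicle_shape": (1.0, 5.0, 2.79, 0.62),
    "stem_lodging": (0.0, 100.0, 24.29, 26.7),
    "mildew": (1.0, 5.0, 3.26, 1.16),
    "saponin": (0.0, 21.0, 10.7, 5.82),
    "tkw": (1.48, 4.9, 2.42, 0.35),
    "seed_yield": (0.18, 5.8, 2.61, 1.03),
}

TRAIT_SUMMARY_CV: dict[str, float] = {
    "dtf": 4.77,
    "emergence": 12.4,
    "homogeneity": 24.2,
    "panicle_length": 5.02,
    "plant_height": 8.44,
    "panicle_density": 17.05,
    "panicle_shape": 7.42,
    "stem_lodging": 54.9,
    "mildew": 17.84,
    "saponin": 19.81,
    "tkw": 10.86,
    "seed_yield": 27.27,
}

# REML variance components from the all-random model, and the published
# pseudo-R² (mixed model) and entry-mean heritability columns:
# (sigma2_g, sigma2_year, sigma2_gxy, sigma2_resid, R2, h2).
VARIANCE_COMPONENTS: dict[str, tuple[float, float, float, float, float, float]] = {
    "dtf": (11.08, 0.0, 5.94, 0.95, 0.95, 0.78),
    "emergence": (36.19, 51.95, 55.58, 119.16, 0.62, 0.43),
    "homogeneity": (327.45, 0.0, 318.10, 155.44, 0.80, 0.64),
    "panicle_length": (2.80, 33.45, 11.85, 29.63, 0.31, 0.20),
    "plant_height": (181.49, 69.82, 135.87, 56.58, 0.90, 0.70),
    "panicle_density": (0.64, 0.41, 0.27, 0.34, 0.77, 0.77),
    "panicle_shape": (0.04, 0.0, 0.14, 0.21, 0.54, 0.29),
    "stem_lodging": (177.18, 56.49, 319.73, 171.27, 0.77, 0.48),
    "mildew": (0.34, 0.0, 0.69, 0.31, 0.78, 0.46),
    "saponin": (4.43, 29.17, 5.48, 9.39, 0.86, 0.51),
    "tkw": (0.06, 0.0, 0.01, 0.02, 0.99, 0.86),
    "seed_yield": (0.51, 0.45, 0.11, 0.20, 0.97, 0.85),
}

# The six traits entering the heritability-weighted selection index, with the
# orientation used there (lower DTF, height, mildew and saponin are desirable).
INDEX_TRAITS: tuple[str, ...] = (
    "tkw",
    "seed_yield",
    "dtf",
    "plant_height",
    "mildew",
    "saponin",
)

# Published per-accession selection index values: accession -> (I 2020, I 2021).
SELECTION_INDEX_BY_YEAR: dict[str, tuple[float, float]] = {
    "QP-002": (-1.31, -0.53),
    "QP-003": (2.38, 0.71),
    "QP-004": (-0.66, -0.28),
    "QP-005": (-1.20, -0.37),
    "QP-006": (-1.76, 2.93),
    "QP-019": (-2.07, -1.80),
    "QP-026": (-1.85, 1.80),
    "QP-030": (-3.15, -0.30),
    "QP-032": (-1.80, -0.64),
    "QP-035": (-1.03, 0.77),
    "QP-036": (-1.12, -0.42),
    "QP-041": (1.06, -0.25),
    "QP-042": (-1.71, -0.81),
    "QP-043": (-2.06, 1.25),
    "QP-046": (-1.77, 1.05),
    "QP-055": (-0.66, 0.92),
    "QP-060": (-0.03, 2.07),
    "QP-061": (-1.21, 0.25),
    "QP-065": (1.72, 2.28),
    "QP-084": (0.88, 3.48),
    "QP-086": (1.00, 3.02),
    "QP-089": (-1.48, 1.97),
    "QP-096": (-1.53, 0.77),
    "QP-097": (-2.52, 0.07),
    "QP-099": (-0.92, 2.29),
    "QP-103": (1.35, 2.53),
    "QP-105": (2.49, 4.31),
    "QP-107": (-5.03, -2.81),
    "QP-108": (-2.38, 1.65),
    "QP-113": (-1.59, 0.73),
    "QP-126": (-1.21, 1.25),
    "QP-127": (0.66, 1.52),
    "QP-128": (-2.64, 0.69),
    "QP-139": (-1.29, 0.26),
    "QP-141": (0.34, 1.76),
    "QP-165": (-3.24, 0.83),
    "QP-169": (-1.20, 1.01),
    "QP-172": (-4.04, -1.18),
    "QP-175": (2.43, 3.05),
    "QP-176": (-2.22, 0.62),
    "QP-181": (-0.96, 0.69),
    "QP-220": (-0.58, 0.20),
    "QP-225": (-0.99, -1.36),
    "QP-231": (-0.03, 1.26),
    "QP-232": (0.25, 1.11),
    "QP-233": (-0.62, 2.10),
    "QP-343": (-2.01, -0.78),
    "QP-346": (1.59, 3.54),
}

# Published absolute between-year index differences (only the accessions the
# study tabulated): accession -> |I_2020 - I_2021|.
INDEX_YEAR_DIFFERENCES: dict[str, float] = {
    "QP-002": 0.78,
    "QP-003": 1.67,
    "QP-004": 0.38,
    "QP-005": 0.82,
    "QP-019": 0.26,
    "QP-032": 1.16,
    "QP-036": 0.70,
    "QP-041": 1.30,
    "QP-042": 0.90,
    "QP-055": 1.58,
    "QP-060": 2.10,
    "QP-061": 1.46,
    "QP-065": 0.56,
    "QP-103": 1.19,
    "QP-105": 1.82,
    "QP-127": 0.85,
    "QP-139": 1.55,
    "QP-141": 1.42,
    "QP-175": 0.62,
    "QP-181": 1.65,
    "QP-220": 0.78,
    "QP-225": 0.37,
    "QP-231": 1.29,
    "QP-232": 0.86,
    "QP-343": 1.23,
}


def trait_summary() -> pd.DataFrame:
    """Published trait summaries as a DataFrame indexed by trait."""
    df = pd.DataFrame.from_dict(
        TRAIT_SUMMARY, orient="index", columns=["min", "max", "mean", "sd"]
    )
    df.index.name = "trait"
    return df


def variance_components() -> pd.DataFrame:
    """Published variance components, pseudo-R² and h², indexed by trait."""
    df = pd.DataFrame.from_dict(
        VARIANCE_COMPONENTS,
        orient="index",
        columns=["sigma2_g", "sigma2_year", "sigma2_gxy", "sigma2_resid", "r2", "h2"],
    )
    df.index.name = "trait"
    return df


def selection_index_table() -> pd.DataFrame:
    """Published per-accession selection index values for 2020 and 2021."""
    df = pd.DataFrame.from_dict(
        SELECTION_INDEX_BY_YEAR, orient="index", columns=["I_2020", "I_2021"]
    )
    df.index.name = "accession"
    return df


def index_year_differences() -> pd.Series:
    """Published |I_2020 - I_2021| for the tabulated accessions."""
    s = pd.Series(INDEX_YEAR_DIFFERENCES, name="abs_difference")
    s.index.name = "accession"
    return s
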