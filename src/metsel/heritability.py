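"""Broad-sense heritability on an entry-mean basis.

For a trait evaluated on G genotypes over J years with K blocks per year, the
variance of a genotype's two-year mean is sigma2_g + sigma2_gxy/J +
sigma2_resid/(J*K), so the proportion attributable to genotype is

    h2 = sigma2_g / (sigma2_g + sigma2_gxy / J + sigma2_resid / (J * K)).

Year, block, block x year and column components shift every entry mean
equally and therefore drop out of the entry-mean variance.  The modeled trial
has J = 2 and K = 3, giving the divisors 2 and 6; the divisors are
parameterized so other designs can reuse the formula unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mixed import VarianceComponents

__all__ = ["HeritabilityResult", "estimate_heritability", "heritability_from_components"]


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    h2: float
    sigma2_g: float
    sigma2_gxy: float
    sigma2_resid: float
    n_years: int
    n_blocks: int


def heritability_from_components(
    sigma2_g: float,
    sigma2_gxy: float,
    sigma2_resid: float,
    n_years: int = 2,
    n_blocks: int = 3,
    trait: str = "",
) -> HeritabilityResult:
    """Entry-mean heritability from the three relevant variance components."""
    if min(sigma2_g, sigma2_gxy, sigma2_resid) < 0:
        raise ValueError("variance components must be non-negative")
    if n_years < 1 or n_blocks < 1:
        raise ValueError("n_years and n_blocks must be >= 1")
    denom = sigma2_g + sigma2_gxy / n_years + sigma2_resid / (n_years * n_blocks)
    if denom == 0.0:
        raise ValueError(
            "all variance components are zero; heritability is undefined"
        )
    return HeritabilityResult(
        trait=trait,
        h2=sigma2_g / denom,
        sigma2_g=sigma2_g,
        sigma2_gxy=sigma2_gxy,
        sigma2_resid=sigma2_resid,
        n_years=n_years,
        n_blocks=n_blocks,
    )


def estimate_heritability(
    vc: VarianceComponents,
    n_years: int = 2,
    n_blocks: int = 3,
    trait: str = "",
) -> HeritabilityResult:
    """Entry-mean heritability from a fitted all-random variance decomposition."""
    try:
        s2g = vc.components["genotype"]
        s2gy = vc.components["genotype:year"]
    except KeyError as err:
        raise ValueError(
            f"variance components missing required term {err}; "
            "fit the all_random model with genotype and genotype:year"
        ) from err
    return heritability_from_components(
        s2g, s2gy, vc.sigma2_resid, n_years=n_years, n_blocks=n_blocks, trait=trait
    )
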