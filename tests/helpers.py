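"""Independent oracles used by the test suite.

These deliberately avoid the package's own REML / Monte-Carlo code paths:
variance components come from closed-form expected-mean-squares (Henderson
method 3) on balanced data, and max-|t| tail probabilities for equicorrelated
families come from numerical integration over the shared latent factor.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def ems_components(data, trait: str):
    """Expected-mean-squares estimators on a balanced genotype x year x block
    layout for the model with genotype, year, genotype x year, block,
    block x year and residual.  Returns (components dict, residual variance);
    estimates may be negative (not truncated) — callers decide interiority.
    """
    df = data.trait_frame(trait)
    I = df["accession"].nunique()
    J = df["year"].nunique()
    K = df["block"].nunique()
    arr = (
        df.set_index(["accession", "year", "block"])["value"]
        .unstack(["year", "block"])
        .to_numpy()
        .reshape(I, J, K)
    )
    m = arr.mean()
    mi = arr.mean(axis=(1, 2))
    mj = arr.mean(axis=(0, 2))
    mk = arr.mean(axis=(0, 1))
    mij = arr.mean(axis=2)
    mjk = arr.mean(axis=0)
    MS_G = J * K * ((mi - m) ** 2).sum() / (I - 1)
    MS_A = I * K * ((mj - m) ** 2).sum() / (J - 1)
    MS_GA = K * ((mij - mi[:, None] - mj[None, :] + m) ** 2).sum() / ((I - 1) * (J - 1))
    MS_B = I * J * ((mk - m) ** 2).sum() / (K - 1)
    MS_BA = I * ((mjk - mj[:, None] - mk[None, :] + m) ** 2).sum() / ((J - 1) * (K - 1))
    SS_E = ((arr - mij[:, :, None] - mjk[None, :, :] + mj[None, :, None]) ** 2).sum()
    MS_E = SS_E / (J * (I - 1) * (K - 1))
    s2e = MS_E
    s2ga = (MS_GA - MS_E) / K
    s2g = (MS_G - MS_GA) / (J * K)
    s2ba = (MS_BA - MS_E) / I
    s2b = (MS_B - MS_BA) / (I * J)
    s2a = (MS_A - MS_GA - I * s2ba) / (I * K)
    comps = {
        "genotype": s2g,
        "year": s2a,
        "genotype:year": s2ga,
        "block": s2b,
        "block:year": s2ba,
    }
    return comps, s2e


def maxt_equicorrelated_p(t: float, m: int, rho: float, df: int) -> float:
    """P(max_j |T_j| >= t) for m equicorrelated (rho >= 0) multivariate-t
    statistics, by Gauss-Hermite quadrature over the shared Gaussian factor
    and adaptive quadrature over the chi scale factor.
    """
    assert 0.0 <= rho < 1.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    sq_r, sq_1mr = np.sqrt(rho), np.sqrt(1.0 - rho)

    def inner(w: float) -> float:
        hi = (t * w - sq_r * nodes) / sq_1mr
        lo = (-t * w - sq_r * nodes) / sq_1mr
        probs = np.clip(stats.norm.cdf(hi) - stats.norm.cdf(lo), 0.0, 1.0)
        return float((weights * probs**m).sum() / np.sqrt(2 * np.pi))

    def integrand(w: float) -> float:
        # density of W = sqrt(chi2_df / df)
        dens = 2.0 * df * w * stats.chi2.pdf(df * w * w, df)
        return inner(w) * dens

    p_below, _ = integrate.quad(integrand, 1e-6, 10.0, limit=200)
    return float(np.clip(1.0 - p_below, 0.0, 1.0))
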