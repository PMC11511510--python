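"""Contrast families, max-|t| adjustment, per-year Pearson correlations."""

import numpy as np
import pandas as pd
import pytest
from helpers import maxt_equicorrelated_p
from scipy import stats

from metsel.data import TrialData
from metsel.inference import (
    adjust_maxt,
    grand_mean_contrasts,
    pearson_ci,
    significance_stars,
    year_contrasts,
)
from metsel.mixed import fit_trait
from metsel.simulate import TrialDesign, VarianceSpec, generate_trial


def _null_trial(seed=0, n_g=12, shift=None):
    spec = {"t": VarianceSpec(mu=10.0, sigma2_block=0.2, sigma2_resid=1.0)}
    shifts = {"t": shift} if shift is not None else None
    return generate_trial(
        TrialDesign(n_genotypes=n_g),
        spec,
        trait_specs={},
        gcorr=None,
        seed=seed,
        genotype_shifts=shifts,
    )


# ------------------------------------------------------------- adjust_maxt
def test_single_hypothesis_equals_raw_t_pvalue():
    p = adjust_maxt(np.array([2.1]), np.eye(1), df=30)
    assert p[0] == pytest.approx(2 * stats.t.sf(2.1, 30), rel=1e-12)


def test_two_independent_hypotheses_approach_sidak():
    t = np.array([2.2, 0.5])
    p_raw = 2 * stats.t.sf(np.abs(t), 2000)
    p_mc = adjust_maxt(t, np.eye(2), df=2000, mc_draws=400_000, seed=3)
    sidak = 1 - (1 - p_raw) ** 2
    assert np.allclose(p_mc, sidak, atol=0.004)
    p_cf = adjust_maxt(t, np.eye(2), df=2000, method="sidak")
    assert np.allclose(p_cf, sidak, rtol=1e-12)


def test_equicorrelated_mc_matches_quadrature_oracle():
    """Monte-Carlo adjusted p agrees with a high-resolution numerical
    integration over the shared latent factor (rho=0.5, m=5)."""
    m, rho, df = 5, 0.5, 60
    C = np.full((m, m), rho)
    np.fill_diagonal(C, 1.0)
    t = np.array([2.8, 1.9, 1.0, 0.3, 2.2])
    draws = 200_000
    p_mc = adjust_maxt(t, C, df=df, mc_draws=draws, seed=9)
    for ti, pi in zip(t, p_mc):
        p_oracle = maxt_equicorrelated_p(abs(ti), m, rho, df)
        se = np.sqrt(p_oracle * (1 - p_oracle) / draws)
        assert abs(pi - p_oracle) < 3 * se + 1e-4


def test_adjusted_p_monotone_in_t_and_at_least_raw():
    t = np.array([0.2, 1.1, 2.3, 3.5])
    C = np.eye(4)
    p = adjust_maxt(t, C, df=50, mc_draws=50_000, seed=1)
    p_raw = 2 * stats.t.sf(np.abs(t), 50)
    assert (np.diff(p) < 0).all()  # larger |t| -> smaller adjusted p
    assert (p >= p_raw).all()


def test_non_psd_correlation_rejected():
    C = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="sidak"):
        adjust_maxt(np.array([1.0, 1.0]), C, df=10)


def test_stars_ladder():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"


# ----------------------------------------------------------- contrast sets
def test_grand_mean_estimates_sum_to_zero():
    d = _null_trial(seed=1)
    _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
    res = grand_mean_contrasts(fx, dm, 2020, mc_draws=5000, seed=0)
    assert res.table["estimate"].sum() == pytest.approx(0.0, abs=1e-10)
    assert len(res.table) == 12


def test_shifted_accession_detected_with_compensating_negatives():
    shift = np.zeros(12)
    shift[4] = 10.0  # +10 residual SDs on one genotype
    d = _null_trial(seed=2, shift=shift)
    _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
    res = grand_mean_contrasts(fx, dm, 2020, mc_draws=20_000, seed=0)
    tab = res.table.set_index("label")
    hot = dm.genotype_levels[4]
    assert tab.loc[hot, "p_adj"] < 0.001
    others = tab.drop(index=hot)
    assert others["estimate"].mean() == pytest.approx(-tab.loc[hot, "estimate"] / 11, rel=1e-6)


def test_year_contrast_definition_and_antisymmetry():
    d = _null_trial(seed=3)
    _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
    res = year_contrasts(fx, dm, mc_draws=5000, seed=0)
    cm = d.cell_means("t").pivot(index="accession", columns="year", values="value")
    for _, row in res.table.iterrows():
        expect = cm.loc[row["label"], 2021] - cm.loc[row["label"], 2020]
        assert row["estimate"] == pytest.approx(expect, abs=1e-8)
    # reversing the year level order flips the estimates
    long = d.long.sort_values("year", ascending=False, kind="stable").reset_index(drop=True)
    swapped = TrialData(long)
    assert swapped.years == [2021, 2020]
    _, fx2, dm2 = fit_trait(swapped, "t", "fixed_gxe", "iid")
    res2 = year_contrasts(fx2, dm2, mc_draws=5000, seed=0)
    merged = res.table.merge(res2.table, on="label", suffixes=("_a", "_b"))
    assert np.allclose(merged["estimate_a"], -merged["estimate_b"], atol=1e-8)


def test_grand_mean_contrast_correlation_closed_form():
    """Under balance, grand-mean contrast t statistics are equicorrelated
    with rho = -1/(m-1)."""
    d = _null_trial(seed=4, n_g=8)
    _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
    from metsel.mixed import cell_mean_matrix

    L, idx = cell_mean_matrix(dm)
    M = L[(idx["year"] == 2020).to_numpy()]
    m = M.shape[0]
    C = (np.eye(m) - np.full((m, m), 1 / m)) @ M
    cov = C @ fx.cov @ C.T
    se = np.sqrt(np.diag(cov))
    corr = cov / np.outer(se, se)
    off = corr[~np.eye(m, dtype=bool)]
    assert np.allclose(off, -1.0 / (m - 1), atol=1e-8)


# ------------------------------------------------------------- correlation
def test_pearson_trivial_cases():
    rows = []
    x = np.arange(1.0, 9.0)
    for i, xv in enumerate(x):
        rows += [
            (f"G{i}", 2020, 1, 1, "a", xv),
            (f"G{i}", 2020, 1, 1, "b", -xv),
            (f"G{i}", 2020, 1, 1, "c", xv),
        ]
    d = TrialData(pd.DataFrame(rows, columns=["accession", "year", "block", "column", "trait", "value"]))
    tab = pearson_ci(d, ["a", "b", "c"], year=2020)
    ab = tab[(tab["trait_1"] == "a") & (tab["trait_2"] == "b")].iloc[0]
    ac = tab[(tab["trait_1"] == "a") & (tab["trait_2"] == "c")].iloc[0]
    assert ab["r"] == pytest.approx(-1.0)
    assert ab["ci_low"] == pytest.approx(-1.0, abs=1e-9)
    assert ab["ci_high"] == pytest.approx(-1.0, abs=1e-9)
    assert ac["r"] == pytest.approx(1.0)
    assert (tab["ci_low"] <= tab["r"]).all() and (tab["r"] <= tab["ci_high"]).all()


def test_pearson_ci_coverage_of_genetic_correlation():
    """Fisher-z CIs on accession means cover the generating genotype-level
    correlation at roughly the nominal rate."""
    from metsel.simulate import GeneticCorrelation

    corr = GeneticCorrelation(("a", "b"), np.array([[1.0, 0.6], [0.6, 1.0]]))
    specs = {
        "a": VarianceSpec(mu=0.0, sigma2_g=1.0, sigma2_resid=0.05),
        "b": VarianceSpec(mu=0.0, sigma2_g=1.0, sigma2_resid=0.05),
    }
    cover = 0
    n_rep = 120
    for seed in range(n_rep):
        d = generate_trial(
            TrialDesign(n_genotypes=48), specs, trait_specs={}, gcorr=corr, seed=seed
        )
        row = pearson_ci(d, ["a", "b"], year=2020).iloc[0]
        cover += row["ci_low"] <= 0.6 <= row["ci_high"]
    assert cover / n_rep == pytest.approx(0.95, abs=0.06)


def test_pearson_errors():
    d = _null_trial(seed=5)
    with pytest.raises(ValueError, match="year"):
        pearson_ci(d, ["t"])
    long = d.long.copy()
    long.loc[long["trait"] == "t", "value"] = 1.0
    long2 = long.copy()
    long2["trait"] = "u"
    both = TrialData(pd.concat([d.long, long2], ignore_index=True))
    with pytest.raises(ValueError, match="zero variance"):
        pearson_ci(both, ["t", "u"], year=2020)
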