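"""REML engine: design construction, oracle equivalence, ANOVA, pseudo-R2."""

import numpy as np
import pytest
from helpers import ems_components

from metsel.data import TrialData
from metsel.mixed import (
    MixedModelError,
    adjusted_cell_means,
    build_design,
    fit_trait,
    pseudo_r2,
    reml_fit,
    wald_anova,
)
from metsel.simulate import TrialDesign, VarianceSpec, generate_trial

FACTORS5 = ("genotype", "year", "genotype:year", "block", "block:year")


# ----------------------------------------------------------------- designs
def test_fixed_design_column_counts():
    d = generate_trial(
        TrialDesign(n_genotypes=2, n_blocks=1),
        {"t": VarianceSpec(mu=1.0, sigma2_resid=1.0)},
        trait_specs={},
        seed=0,
    )
    dm = build_design(d, "t", "fixed_gxe")
    # intercept + 1 genotype + 1 year + 1 interaction
    assert dm.X.shape[1] == 4
    assert dm.colnames[0] == "Intercept"


def test_all_random_has_six_incidence_matrices(default_trial):
    dm = build_design(default_trial, "dtf", "all_random")
    assert [t.name for t in dm.terms] == [
        "genotype",
        "year",
        "genotype:year",
        "block",
        "block:year",
        "column",
    ]
    for t in dm.terms:
        assert t.Z.shape[0] == dm.n and np.allclose(t.Z.sum(axis=1), 1.0)


def test_coefficient_names_round_trip(default_trial):
    dm = build_design(default_trial, "dtf", "fixed_gxe")
    mapping = dm.coefficient_factors()
    names = [n for n in dm.colnames if n != "Intercept"]
    assert len(set(names)) == len(names)
    for name in names:
        term, levels = mapping[name]
        assert term in ("genotype", "year", "genotype:year")
        rebuilt = f"{term}[{'|'.join(str(l) for l in levels)}]"
        assert rebuilt == name


def test_single_year_gxe_design_errors():
    d = generate_trial(
        TrialDesign(n_genotypes=3, n_years=1),
        {"t": VarianceSpec(mu=1.0, sigma2_resid=1.0)},
        trait_specs={},
        seed=0,
    )
    with pytest.raises(MixedModelError, match="2 years"):
        build_design(d, "t", "fixed_gxe")


# ---------------------------------------------------------------- REML fits
def test_reml_matches_ems_oracle_when_interior():
    """Primary oracle: on balanced data REML equals the closed-form
    expected-mean-squares estimators to 1e-6 relative tolerance whenever the
    EMS solution is interior."""
    spec = {
        "t": VarianceSpec(
            mu=50.0,
            sigma2_g=8.0,
            sigma2_year=4.0,
            sigma2_gxy=3.0,
            sigma2_block=2.0,
            sigma2_blockxyear=1.5,
            sigma2_resid=2.0,
        )
    }
    interior_checked = 0
    for n_g, seed in [(4, 23), (8, 23), (8, 5), (6, 11), (8, 31)]:
        d = generate_trial(
            TrialDesign(n_genotypes=n_g), spec, trait_specs={}, gcorr=None, seed=seed
        )
        ems, s2e = ems_components(d, "t")
        if min(ems.values()) <= 0:
            continue
        dm = build_design(d, "t", "all_random", random_factors=FACTORS5)
        vc, _ = reml_fit(dm)
        for k, v in ems.items():
            assert vc.components[k] == pytest.approx(v, rel=1e-6, abs=1e-9)
        assert vc.sigma2_resid == pytest.approx(s2e, rel=1e-6)
        interior_checked += 1
    assert interior_checked >= 2


def test_pure_noise_pins_genotype_variance_at_boundary():
    """Pure-residual data: the genotype variance is small, and in draws whose
    unconstrained optimum is negative it is pinned at exactly zero with a
    boundary flag."""
    spec = {"t": VarianceSpec(mu=3.0, sigma2_resid=2.0)}
    estimates = []
    for seed in range(8):
        d = generate_trial(TrialDesign(n_genotypes=8), spec, trait_specs={}, seed=seed)
        dm = build_design(d, "t", "all_random", random_factors=("genotype",))
        vc, _ = reml_fit(dm)
        estimates.append(vc.components["genotype"])
        if vc.components["genotype"] == 0.0:
            assert "genotype" in vc.boundary
            sample_var = np.var(d.long["value"], ddof=1)
            assert vc.sigma2_resid == pytest.approx(sample_var, rel=0.05)
    assert np.mean(estimates) < 0.5  # small relative to sigma2_resid = 2
    assert any(e == 0.0 for e in estimates)


def test_gls_cell_means_equal_arithmetic_means_in_balance(default_trial):
    vc, fx, dm = fit_trait(default_trial, "plant_height", "fixed_gxe", "hetero_corr")
    model_means = adjusted_cell_means(fx, dm)
    arith = default_trial.cell_means("plant_height")
    merged = model_means.merge(arith, on=["accession", "year"])
    assert np.allclose(merged["mean"], merged["value"], atol=1e-7)


def test_scale_invariance_of_components_and_anova(small_interior_trial):
    d = small_interior_trial
    vc1, fx1, dm1 = fit_trait(d, "t", "fixed_gxe", "iid")
    a1 = wald_anova(fx1, dm1)
    scaled = TrialData(d.long.assign(value=d.long["value"] * 3.0))
    vc2, fx2, dm2 = fit_trait(scaled, "t", "fixed_gxe", "iid")
    a2 = wald_anova(fx2, dm2)
    assert vc2.components["block"] == pytest.approx(9.0 * vc1.components["block"], rel=1e-4)
    assert vc2.sigma2_resid == pytest.approx(9.0 * vc1.sigma2_resid, rel=1e-4)
    assert np.allclose(a1["F"], a2["F"], rtol=1e-6)


def test_hetero_corr_recovers_residual_correlation():
    spec = {
        "t": VarianceSpec(
            mu=10.0, sigma2_resid=2.0, residual_year_corr=0.6,
            year_residual_scales=(1.0, 1.5),
        )
    }
    rhos, ratios = [], []
    for seed in range(10):
        d = generate_trial(TrialDesign(), spec, trait_specs={}, seed=seed)
        vc, _, _ = fit_trait(d, "t", "fixed_gxe", "hetero_corr")
        rhos.append(vc.residual_corr)
        ratios.append(vc.residual_variances[1] / vc.residual_variances[0])
    assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)
    assert np.mean(ratios) == pytest.approx(1.5**2, rel=0.15)


# -------------------------------------------------------------------- ANOVA
def test_strong_genotype_effect_is_highly_significant(default_trial):
    """A panel with large genotype variance relative to noise shows genotype
    differences at p < 0.001, matching universal significance in trials of
    this size."""
    _, fx, dm = fit_trait(default_trial, "plant_height", "fixed_gxe", "iid")
    an = wald_anova(fx, dm).set_index("term")
    assert an.loc["genotype", "p"] < 0.001
    assert an.loc["genotype:year", "p"] < 0.001


def test_year_f_invariant_to_genotype_relabeling(small_interior_trial):
    d = small_interior_trial
    _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
    f_year = wald_anova(fx, dm).set_index("term").loc["year", "F"]
    long = d.long.copy()
    perm = {a: b for a, b in zip(d.accessions, np.roll(d.accessions, 2))}
    long["accession"] = long["accession"].map(perm)
    _, fx2, dm2 = fit_trait(TrialData(long), "t", "fixed_gxe", "iid")
    f_year2 = wald_anova(fx2, dm2).set_index("term").loc["year", "F"]
    assert f_year == pytest.approx(f_year2, rel=1e-8)


def test_genotype_pvalues_uniform_under_null():
    """With no genotype signal, the genotype F test's p-values are roughly
    uniform over replicate simulations (type-I calibration)."""
    spec = {"t": VarianceSpec(mu=0.0, sigma2_block=0.2, sigma2_resid=1.0)}
    ps = []
    for seed in range(120):
        d = generate_trial(TrialDesign(n_genotypes=6), spec, trait_specs={}, seed=seed)
        _, fx, dm = fit_trait(d, "t", "fixed_gxe", "iid")
        ps.append(wald_anova(fx, dm).set_index("term").loc["genotype", "p"])
    ps = np.asarray(ps)
    assert np.mean(ps < 0.05) == pytest.approx(0.05, abs=0.06)
    assert np.mean(ps) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------- pseudo-R2
def test_pseudo_r2_bounds_and_permutation(default_trial):
    _, fx, dm = fit_trait(default_trial, "plant_height", "fixed_gxe", "iid")
    r2 = pseudo_r2(fx, dm)
    assert 0.0 < r2 <= 1.0
    # permuting observations destroys the genotype signal the fit explains
    long = default_trial.long.copy()
    ph = long["trait"] == "plant_height"
    rng = np.random.default_rng(0)
    long.loc[ph, "value"] = rng.permutation(long.loc[ph, "value"].to_numpy())
    _, fxp, dmp = fit_trait(TrialData(long), "plant_height", "fixed_gxe", "iid")
    assert pseudo_r2(fxp, dmp) < r2


def test_pseudo_r2_trivial_cases(small_interior_trial):
    _, fx, dm = fit_trait(small_interior_trial, "t", "fixed_gxe", "iid")
    perfect = fx
    perfect.fitted_conditional = fx.y.copy()
    assert pseudo_r2(perfect, dm) == pytest.approx(1.0)
    perfect.fitted_conditional = np.full_like(fx.y, fx.y.mean())
    assert pseudo_r2(perfect, dm) == 0.0
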