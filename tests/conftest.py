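import numpy as np
import pytest

from metsel.simulate import TrialDesign, VarianceSpec, generate_trial


@pytest.fixture(scope="session")
def small_interior_trial():
    """Balanced 6 x 2 x 3 trial with all generating components well away from
    zero, so closed-form EMS estimators are usually interior."""
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
    return generate_trial(
        TrialDesign(n_genotypes=6), spec, trait_specs={}, gcorr=None, seed=11
    )


@pytest.fixture(scope="session")
def default_trial():
    """One realization of the default 48 x 2 x 3 panel."""
    return generate_trial(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
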