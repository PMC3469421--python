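import numpy as np
import pandas as pd
import pytest

from decayqtl import SimConfig, simulate_study

TIME_POINTS = np.array([0.0, 0.5, 1.0, 2.0, 4.0])


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 200 genes x 50 individuals, sigma = 0.2."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_study():
    """Exact-mode noiseless study for identity checks."""
    cfg = SimConfig(seed=2, n_genes=80, n_individuals=15, noise_sd_log2=0.0)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Global-null study: no planted effects, no inter-individual decay variation."""
    cfg = SimConfig(
        seed=3, frac_rdqtl=0.0, frac_eqtl_baseline=0.0, sd_log2_k_individual=0.0
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ols_oracle(x, y):
    """Independent normal-equations oracle (statsmodels OLS with intercept)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return {
        "slope": fit.params[1],
        "intercept": fit.params[0],
        "se": fit.bse[1],
        "t": fit.tvalues[1],
        "p": fit.pvalues[1],
        "resid": fit.resid,
    }
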