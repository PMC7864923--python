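import numpy as np
import pytest

import twinace as ta


@pytest.fixture(scope="session")
def ae_spec():
    """Univariate AE generating model with a² = 0.64 (the conscientiousness
    fit used throughout as a reference parameterization)."""
    return ta.univariate_spec(a=np.sqrt(0.64), e=np.sqrt(0.36), mean=3.13, scale=0.41)


@pytest.fixture(scope="session")
def ae_data(ae_spec):
    """Mid-sized AE dataset (400 MZ / 300 DZ pairs)."""
    return ta.simulate(ae_spec, 400, 300, seed=11)


@pytest.fixture(scope="session")
def study_data():
    """Four-trait dataset at the study's sample sizes (1135 MZ / 823 DZ)."""
    return ta.simulate(ta.study_mirror_spec(), ta.STUDY_N_MZ, ta.STUDY_N_DZ, seed=7)


@pytest.fixture(scope="session")
def table1_correlation_matrix():
    """The published 4×4 simple-correlation matrix of the four
    conscientiousness measures."""
    R = np.eye(4)
    vals = {
        (0, 1): 0.79, (0, 2): 0.79, (0, 3): 0.79,
        (1, 2): 0.77, (1, 3): 0.75, (2, 3): 0.74,
    }
    for (i, j), v in vals.items():
        R[i, j] = R[j, i] = v
    return R


def dense_minus2ll(data, traits, mu, sigma):
    """Independent oracle: per-family -2 log multivariate-normal density of
    the observed subvector, computed row by row with scipy."""
    from scipy.stats import multivariate_normal

    total = 0.0
    for zyg in ("MZ", "DZ"):
        X = data.phenotype_matrix(traits, zyg)
        S = sigma[zyg]
        for row in X:
            obs = ~np.isnan(row)
            if not obs.any():
                continue
            total += -2.0 * multivariate_normal.logpdf(
                row[obs], mean=mu[obs], cov=S[np.ix_(obs, obs)]
            )
    return total
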