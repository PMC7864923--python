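import numpy as np
import pandas as pd
import pytest

import twinace as ta
from twinace.fiml import LOG_2PI
from twinace.saturated import SaturatedModel
from twinace.univariate import (
    UnivariateBiometricModel,
    profile_bounds,
)

from conftest import dense_minus2ll


def _one_family(zyg="MZ", t1=0.0, t2=np.nan):
    frame = pd.DataFrame(
        [{"family_id": "f", "zygosity": zyg, "age": 12.0, "sex1": 0,
          "sex2": 0, "t1": t1, "t2": t2}]
    )
    return ta.TwinDataset(frame, ["t"])


def test_single_observation_standard_normal_density():
    """One twin observed, model mean 0 / variance 1, observation 0:
    -2lnL = ln(2π)."""
    ds = _one_family(t1=0.0, t2=np.nan)
    model = UnivariateBiometricModel(ds, "t", "AE")
    val = model.minus2ll(paths=[np.sqrt(0.5), np.sqrt(0.5)], mean=0.0)
    assert val == pytest.approx(LOG_2PI, abs=1e-12)


def test_fiml_equals_dense_per_family_likelihood_with_missingness(ae_data):
    """Pattern-grouped FIML must equal a family-by-family scipy evaluation,
    including with missing co-twins."""
    frame = ae_data.frame.copy()
    rng = np.random.default_rng(0)
    drop = rng.random(len(frame)) < 0.15
    frame.loc[drop, "trait12"] = np.nan
    ds = ta.TwinDataset(frame, ["trait1"])
    model = UnivariateBiometricModel(ds, "trait1", "ACE")
    paths = [0.6, 0.3, 0.55]
    mean = 3.1
    got = model.minus2ll(paths, mean)
    variances = dict(zip("ACE", [p**2 for p in paths]))
    sigma = {
        z: ta.univariate_spec(
            a=paths[0], c=paths[1], e=paths[2]
        ).implied_twin_covariance(z)
        for z in ("MZ", "DZ")
    }
    expected = dense_minus2ll(ds, ["trait1"], np.array([mean, mean]), sigma)
    assert got == pytest.approx(expected, rel=1e-10)


def test_fiml_equals_closed_form_on_complete_data(ae_data):
    """With no missing values, FIML equals the two-group closed-form
    multivariate-normal -2lnL computed from sample moments."""
    fit = ta.fit_univariate(ae_data, "trait1", "AE", n_restarts=2)
    total = 0.0
    for zyg in ("MZ", "DZ"):
        X = ae_data.trait_pairs("trait1", zyg)
        n = len(X)
        mu = np.array([fit.mean, fit.mean])
        S = fit.implied_pair_covariance(zyg)
        Si = np.linalg.inv(S)
        d = X - mu
        quad = np.einsum("ni,ij,nj->", d, Si, d)
        total += n * (2 * LOG_2PI + np.log(np.linalg.det(S))) + quad
    assert fit.minus2ll == pytest.approx(total, rel=1e-6)


def test_duplicating_families_doubles_minus2ll(ae_data):
    doubled = ta.TwinDataset(
        pd.concat([ae_data.frame, ae_data.frame], ignore_index=True),
        ae_data.traits,
    )
    m1 = UnivariateBiometricModel(ae_data, "trait1", "AE")
    m2 = UnivariateBiometricModel(doubled, "trait1", "AE")
    v1 = m1.minus2ll([0.7, 0.5], 3.0)
    v2 = m2.minus2ll([0.7, 0.5], 3.0)
    assert v2 == pytest.approx(2 * v1, rel=1e-12)


def test_saturated_closed_form_and_df(ae_data):
    sat = SaturatedModel(ae_data, ["trait1"]).fit()
    assert sat.n_free == 10
    assert sat.df == ae_data.n_families * 2 - 10
    # closed form check at group moments
    total = 0.0
    for zyg in ("MZ", "DZ"):
        X = ae_data.trait_pairs("trait1", zyg)
        n = len(X)
        C = np.cov(X.T, ddof=0)
        total += n * (2 * LOG_2PI + np.log(np.linalg.det(C)) + 2)
    assert sat.minus2ll == pytest.approx(total, rel=1e-10)


def test_saturated_with_missing_matches_dense_oracle(ae_data):
    frame = ae_data.frame.copy()
    rng = np.random.default_rng(1)
    frame.loc[rng.random(len(frame)) < 0.2, "trait11"] = np.nan
    ds = ta.TwinDataset(frame, ["trait1"])
    sat = SaturatedModel(ds, ["trait1"]).fit()
    sigma = {z: sat.covariances[z] for z in ("MZ", "DZ")}
    # evaluate the dense oracle at the numeric optimum, per group
    total = 0.0
    for zyg in ("MZ", "DZ"):
        sub = ds.subset(zyg)
        total += dense_minus2ll(
            sub, ["trait1"], sat.means[zyg], {zyg: sigma[zyg], ("DZ" if zyg == "MZ" else "MZ"): sigma[zyg]}
        )
    assert sat.minus2ll == pytest.approx(total, rel=1e-8)


def test_nesting_inequalities(ae_data):
    sat = SaturatedModel(ae_data, ["trait1"]).fit()
    fits = {
        m: ta.fit_univariate(ae_data, "trait1", m, n_restarts=2)
        for m in ("ACE", "AE", "CE", "E")
    }
    assert sat.minus2ll <= fits["ACE"].minus2ll + 1e-6
    assert fits["ACE"].minus2ll <= fits["AE"].minus2ll + 1e-6
    assert fits["ACE"].minus2ll <= fits["CE"].minus2ll + 1e-6
    assert fits["AE"].minus2ll <= fits["E"].minus2ll + 1e-6
    assert fits["CE"].minus2ll <= fits["E"].minus2ll + 1e-6


def test_standardized_components_sum_to_one(ae_data):
    for m in ("ACE", "AE", "E"):
        fit = ta.fit_univariate(ae_data, "trait1", m, n_restarts=2)
        assert sum(fit.standardized.values()) == pytest.approx(1.0, abs=1e-6)


def test_e_only_data_yields_unit_e2():
    ds = ta.simulate(ta.univariate_spec(e=1.0), 2000, 1500, seed=19)
    for m in ("E", "AE"):
        fit = ta.fit_univariate(ds, "trait1", m, n_restarts=2)
        assert fit.standardized["E"] >= 0.99


def test_de_model_rejected(ae_data):
    with pytest.raises(ta.UnsupportedModelError):
        UnivariateBiometricModel(ae_data, "trait1", "DE")


def test_fit_invariant_to_twin_order_and_family_order(ae_data):
    rng = np.random.default_rng(2)
    swapped = ae_data.swap_twin_order(rng.integers(0, 2, ae_data.n_families))
    shuffled = ta.TwinDataset(
        swapped.frame.sample(frac=1.0, random_state=3), swapped.traits
    )
    f1 = ta.fit_univariate(ae_data, "trait1", "AE", n_restarts=2)
    f2 = ta.fit_univariate(shuffled, "trait1", "AE", n_restarts=2)
    assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-5)
    assert f1.standardized["A"] == pytest.approx(f2.standardized["A"], abs=1e-4)


def test_profile_bounds_quadratic_gives_wald_interval():
    """On a quadratic -2lnL surface the profile bounds are θ̂ ± 1.96 s."""
    theta_hat, s = 0.5, 0.07
    thr = 3.841458820694124

    def g(v):
        return (v - theta_hat) ** 2 / s**2 - thr

    (lo, lo_c), (hi, hi_c) = profile_bounds(g, theta_hat, lower=0.0, upper=1.0)
    half = 1.959963984540054 * s
    assert lo == pytest.approx(theta_hat - half, abs=1e-4)
    assert hi == pytest.approx(theta_hat + half, abs=1e-4)
    assert not lo_c and not hi_c


def test_boundary_estimate_gives_clipped_one_sided_interval():
    """Fitting ACE to AE data puts ĉ² at the 0 boundary: lo = 0 flagged,
    hi > 0."""
    ds = ta.simulate(
        ta.univariate_spec(a=np.sqrt(0.63), e=np.sqrt(0.37)), 1135, 823, seed=41
    )
    fit = ta.fit_univariate(ds, "trait1", "ACE", n_restarts=3)
    ci = fit.profile_ci("c2")
    if fit.standardized["C"] < 1e-4:
        assert ci.lo == 0.0 and ci.lo_at_boundary
    assert ci.hi > ci.lo


def test_profile_ci_brackets_estimate(ae_data):
    fit = ta.fit_univariate(ae_data, "trait1", "AE", n_restarts=2)
    ci = fit.profile_ci("a2")
    assert 0.0 <= ci.lo <= fit.standardized["A"] <= ci.hi <= 1.0
    assert ci.hi - ci.lo < 0.3
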