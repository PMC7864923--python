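import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import twinace as ta
from twinace.phenotypic import (
    correlation_matrix,
    descriptives,
    intraclass_correlation,
    table1_report,
)


def _dataset(pairs_by_zyg, trait="t"):
    rows = []
    for zyg, pairs in pairs_by_zyg.items():
        for i, (a, b) in enumerate(pairs):
            rows.append(
                {"family_id": f"{zyg}{i}", "zygosity": zyg, "age": 12.0,
                 "sex1": 0, "sex2": 0, f"{trait}1": a, f"{trait}2": b}
            )
    return ta.TwinDataset(pd.DataFrame(rows), [trait])


def test_descriptives_constant_and_two_point():
    ds = _dataset({"MZ": [(3.13, 3.13), (3.13, 3.13)]})
    d = descriptives(ds)
    assert d.loc["t", "mean"] == pytest.approx(3.13)
    assert d.loc["t", "sd"] == pytest.approx(0.0)
    ds2 = _dataset({"MZ": [(0.0, 2.0), (np.nan, np.nan), (np.nan, np.nan)]})
    d2 = descriptives(ds2)
    assert d2.loc["t", "mean"] == pytest.approx(1.0)
    assert d2.loc["t", "sd"] == pytest.approx(np.sqrt(2.0))  # n-1 denominator


def test_all_missing_trait_reported_missing_not_error():
    ds = _dataset({"MZ": [(np.nan, np.nan)] * 3})
    d = descriptives(ds)
    assert np.isnan(d.loc["t", "mean"]) and np.isnan(d.loc["t", "sd"])


def test_duplicated_trait_correlates_perfectly(ae_data):
    frame = ae_data.frame.copy()
    frame["copy1"] = frame["trait11"]
    frame["copy2"] = frame["trait12"]
    ds = ta.TwinDataset(frame, ["trait1", "copy"])
    R, reports = correlation_matrix(ds)
    assert R.loc["trait1", "copy"] == pytest.approx(1.0)
    (rep,) = reports
    assert rep.lo <= rep.r <= rep.hi


def test_partial_equals_simple_when_covariates_have_no_effect():
    from dataclasses import replace

    null_spec = replace(ta.study_mirror_spec(), beta_age=None, beta_sex=None)
    data = ta.simulate(null_spec, 1135, 823, seed=23)
    R_simple, _ = correlation_matrix(data)
    R_partial, _ = correlation_matrix(data, partial_on=("age", "sex"))
    diff = (R_simple - R_partial).abs().to_numpy()
    assert diff.max() < 1e-2


def test_study_simulation_correlations_in_published_band(study_data):
    R, _ = correlation_matrix(study_data)
    off = R.to_numpy()[np.triu_indices(4, 1)]
    assert np.all((off >= 0.72) & (off <= 0.81))


def test_icc_perfect_concordance():
    ds = _dataset({"MZ": [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]})
    assert intraclass_correlation(ds, "t", "MZ").r == pytest.approx(1.0)


def test_icc_null_for_independent_members():
    ds = ta.simulate(ta.univariate_spec(e=1.0), 50_000, 0, seed=3)
    icc = intraclass_correlation(ds, "trait1", "MZ")
    assert abs(icc.r) < 3 / np.sqrt(50_000)


def test_icc_matches_implied_cross_twin_correlation():
    spec = ta.univariate_spec(a=np.sqrt(0.54), c=np.sqrt(0.10), e=np.sqrt(0.36))
    ds = ta.simulate(spec, 100_000, 100_000, seed=29)
    se = 1.0 / np.sqrt(100_000)
    assert abs(intraclass_correlation(ds, "trait1", "MZ").r - 0.64) < 3 * se
    assert abs(intraclass_correlation(ds, "trait1", "DZ").r - 0.37) < 3 * se


def test_icc_invariant_to_twin_order_swap(ae_data):
    rng = np.random.default_rng(5)
    mask = rng.integers(0, 2, ae_data.n_families).astype(bool)
    swapped = ae_data.swap_twin_order(mask)
    for zyg in ("MZ", "DZ"):
        a = intraclass_correlation(ae_data, "trait1", zyg).r
        b = intraclass_correlation(swapped, "trait1", zyg).r
        assert a == pytest.approx(b, abs=1e-12)


def test_icc_is_the_constrained_ml_optimum():
    """Cross-check the closed form against direct numerical maximization of
    the equal-mean equal-variance bivariate normal likelihood."""
    ds = ta.simulate(ta.univariate_spec(a=0.7, e=0.71), 300, 0, seed=7)
    P = ds.trait_pairs("trait1", "MZ")
    r_hat = intraclass_correlation(ds, "trait1", "MZ").r

    def m2ll(theta):
        mu, logs2, z = theta
        s2, r = np.exp(logs2), np.tanh(z)
        S = s2 * np.array([[1, r], [r, 1]])
        Si = np.linalg.inv(S)
        d = P - mu
        quad = np.einsum("ni,ij,nj->", d, Si, d)
        return len(P) * np.log(np.linalg.det(S)) + quad

    res = minimize(m2ll, [P.mean(), np.log(P.var()), np.arctanh(0.3)],
                   method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    assert r_hat == pytest.approx(np.tanh(res.x[2]), abs=1e-5)


def test_icc_insufficient_pairs():
    ds = _dataset({"MZ": [(1.0, 2.0), (2.0, 1.0)]})
    with pytest.raises(ta.InsufficientDataError):
        intraclass_correlation(ds, "t", "MZ")


def test_table1_report_shape(study_data):
    t1 = table1_report(study_data)
    assert list(t1.index) == list(ta.STUDY_TRAITS)
    for col in ("mean", "sd", "icc_MZ", "icc_DZ"):
        assert col in t1.columns
    # simple (below diagonal) and partial (above) entries filled
    assert not np.isnan(t1.loc["grit", "conscientiousness"])
    assert not np.isnan(t1.loc["conscientiousness", "grit"])
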