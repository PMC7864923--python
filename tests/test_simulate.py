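import numpy as np
import pytest

import twinace as ta


def test_empty_simulation():
    ds = ta.simulate(ta.univariate_spec(a=0.6, e=0.8), 0, 0, seed=0)
    assert ds.n_families == 0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ta.simulate(ta.univariate_spec(e=1.0), -1, 0, seed=0)


def test_same_seed_identical_different_seed_differs():
    spec = ta.study_mirror_spec()
    a = ta.simulate(spec, 30, 30, seed=9)
    b = ta.simulate(spec, 30, 30, seed=9)
    c = ta.simulate(spec, 30, 30, seed=10)
    assert a.frame.equals(b.frame)
    assert not a.frame.equals(c.frame)


def test_mz_sex_identical_dz_opposite_sex_allowed():
    ds = ta.simulate(ta.univariate_spec(a=0.6, e=0.8), 300, 300, seed=1)
    f = ds.frame
    mz = f[f["zygosity"] == "MZ"]
    dz = f[f["zygosity"] == "DZ"]
    assert (mz["sex1"] == mz["sex2"]).all()
    assert (dz["sex1"] != dz["sex2"]).any()


def test_age_shared_within_pair_and_in_range():
    ds = ta.simulate(ta.study_mirror_spec(), 100, 100, seed=2)
    assert ds.frame["age"].between(9, 18).all()


def _no_covariates(spec):
    """Implied covariances describe the covariate-free scores, so strip the
    generator's age/sex effects before comparing raw moments."""
    from dataclasses import replace

    return replace(spec, beta_age=None, beta_sex=None)


@pytest.mark.parametrize(
    "make_spec",
    [
        lambda: ta.univariate_spec(a=np.sqrt(0.54), c=np.sqrt(0.10), e=np.sqrt(0.36)),
        lambda: _no_covariates(ta.study_mirror_spec()).to_cholesky(),
        lambda: _no_covariates(ta.study_mirror_spec()).to_independent_pathway(),
        lambda: _no_covariates(ta.study_mirror_spec()),
    ],
    ids=["univariate-ACE", "cholesky", "independent-pathway", "common-pathway"],
)
def test_sample_covariance_converges_to_implied(make_spec):
    """At n = 10⁵ pairs the empirical twin covariance matches the implied
    matrix within 3 Monte-Carlo standard errors, for every structure."""
    spec = make_spec()
    n = 100_000
    ds = ta.simulate(spec, n, 0, seed=31)
    X = ds.phenotype_matrix(zygosity="MZ")
    emp = np.cov(X, rowvar=False, ddof=1)
    ref = spec.implied_twin_covariance("MZ")
    # MC SE of a covariance entry ~ sqrt((s_ii s_jj + s_ij^2)/n)
    d = np.sqrt(np.diag(ref))
    se = np.sqrt((np.outer(d**2, d**2) + ref**2) / n)
    assert np.all(np.abs(emp - ref) < 3.5 * se)


def test_mz_cross_covariance_close_to_implied_value():
    """100k MZ pairs under ACE(0.54, 0.10, 0.36): cross-twin covariance
    within 3 SEs of 0.64."""
    spec = ta.univariate_spec(a=np.sqrt(0.54), c=np.sqrt(0.10), e=np.sqrt(0.36))
    ds = ta.simulate(spec, 100_000, 0, seed=13)
    P = ds.trait_pairs("trait1", "MZ")
    emp = np.cov(P[:, 0], P[:, 1])[0, 1]
    se = np.sqrt((1.0 + 0.64**2) / 100_000)
    assert abs(emp - 0.64) < 3 * se


def test_likert_output_on_grid():
    ds = ta.simulate(ta.study_mirror_spec(), 50, 50, seed=5, likert=True)
    vals = ds.phenotype_matrix()
    assert np.isin(vals, [1, 2, 3, 4, 5]).all()


class TestStudyMirrorSpec:
    """The returned spec must imply the study's published summary ranges."""

    spec = ta.study_mirror_spec()

    def test_heritabilities(self):
        h2 = self.spec.implied_standardized_components()["A"]
        assert np.all((h2 >= 0.62) & (h2 <= 0.64 + 1e-9))

    def test_phenotypic_correlations_within_printed_rounding(self):
        R = self.spec.implied_phenotypic_correlation()
        off = R[np.triu_indices(4, 1)]
        assert np.all((off >= 0.735) & (off <= 0.795))
        # grit vs conscientiousness specifically
        assert 0.74 <= R[0, 3] <= 0.79

    def test_genetic_and_environmental_correlations(self):
        rg = self.spec.implied_component_correlation("A")[np.triu_indices(4, 1)]
        re = self.spec.implied_component_correlation("E")[np.triu_indices(4, 1)]
        assert np.all((rg >= 0.82) & (rg <= 0.91))
        assert np.all((re >= 0.56) & (re <= 0.62))

    def test_dz_intraclass_in_printed_range(self):
        dz = self.spec.implied_intraclass_correlation("DZ")
        assert np.all((dz >= 0.28) & (dz <= 0.35))

    def test_factor_heritability_near_reported(self):
        a_f2 = self.spec.params["factor"]["A"] ** 2
        assert a_f2 == pytest.approx(0.72, abs=0.02)

    def test_descriptives_at_study_n(self):
        ds = ta.simulate(self.spec, 1135, 823, seed=17)
        desc = ta.descriptives(ds)
        assert np.all(np.abs(desc["mean"].to_numpy() - [3.13, 3.15, 3.13, 3.14]) < 0.05)
        assert np.all(np.abs(desc["sd"].to_numpy() - [0.41, 0.52, 0.47, 0.42]) < 0.05)
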