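import numpy as np
import pytest

import twinace as ta
from twinace.generative import GenerativeSpec, _chol_lower
from twinace.multivariate import (
    MultivariateBiometricModel,
    model_degrees_of_freedom,
    n_free_parameters,
)
from twinace.saturated import SaturatedModel


def test_free_parameter_counts_for_four_traits():
    assert n_free_parameters("cholesky", ("A", "E"), 4) == 24
    assert n_free_parameters("independent_pathway", ("A", "E"), 4) == 20
    assert n_free_parameters("common_pathway", ("A", "E"), 4) == 17
    assert n_free_parameters("common_pathway", ("A", "C", "E"), 4) == 22
    assert n_free_parameters("univariate", ("A", "C", "E"), 1) == 4


def test_df_ladder_on_study_sized_fixture(study_data):
    assert model_degrees_of_freedom(
        "univariate", ("A", "C", "E"), 1, study_data,
        traits=["conscientiousness"],
    ) == 3912
    assert model_degrees_of_freedom("cholesky", ("A", "E"), 4, study_data) == 15640
    assert model_degrees_of_freedom(
        "independent_pathway", ("A", "E"), 4, study_data
    ) == 15644
    assert model_degrees_of_freedom(
        "common_pathway", ("A", "E"), 4, study_data
    ) == 15647


def test_invalid_component_combination_rejected(study_data):
    with pytest.raises(ta.NotIdentifiedError):
        model_degrees_of_freedom("cholesky", ("A", "C", "D", "E"), 4, study_data)


def test_k1_cholesky_reduces_to_univariate(ae_data):
    uni = ta.fit_univariate(ae_data, "trait1", "AE", n_restarts=2)
    mv = ta.fit_multivariate(
        ae_data, ["trait1"], structure="cholesky", components=("A", "E"),
        n_restarts=2,
    )
    assert mv.minus2ll == pytest.approx(uni.minus2ll, abs=1e-5)
    std = mv.spec.implied_standardized_components()
    assert std["A"][0] == pytest.approx(uni.standardized["A"], abs=1e-4)


def test_structure_nesting_on_study_data(study_data):
    fits = {
        s: ta.fit_multivariate(study_data, structure=s, n_restarts=2)
        for s in ("cholesky", "independent_pathway", "common_pathway")
    }
    sat = SaturatedModel(study_data).fit()
    assert sat.minus2ll <= fits["cholesky"].minus2ll + 1e-4
    assert fits["cholesky"].minus2ll <= fits["independent_pathway"].minus2ll + 1e-4
    assert (
        fits["independent_pathway"].minus2ll
        <= fits["common_pathway"].minus2ll + 1e-4
    )


def test_correlated_factors_hand_arithmetic():
    """A-paths rows (0.8, 0) / (0.4, 0.6): A = LLᵀ, r_G = 0.32/√(0.64·0.52)."""
    L_A = np.array([[0.8, 0.0], [0.4, 0.6]])
    L_E = np.array([[0.6, 0.0], [0.1, 0.5]])
    spec = GenerativeSpec("cholesky", ("A", "E"), {"A": L_A, "E": L_E})
    A = spec.component_covariance("A")
    assert np.allclose(A, [[0.64, 0.32], [0.32, 0.52]])
    from twinace.multivariate import MultivariateResults

    fit = MultivariateResults(
        structure="cholesky", components=("A", "E"), traits=spec.traits,
        spec=spec, means=np.zeros(2), minus2ll=0.0, n_free=0, n_obs=0, df=0,
        converged=True,
    )
    sol = fit.correlated_factors_solution()
    assert sol.r_g[0, 1] == pytest.approx(0.32 / np.sqrt(0.64 * 0.52), abs=1e-12)
    assert np.allclose(np.diag(sol.r_g), 1.0)


def test_diagonal_a_paths_give_identity_genetic_correlation():
    spec = GenerativeSpec(
        "cholesky", ("A", "E"),
        {"A": np.diag([0.7, 0.6]), "E": np.diag([0.5, 0.5])},
    )
    from twinace.multivariate import MultivariateResults

    fit = MultivariateResults(
        structure="cholesky", components=("A", "E"), traits=spec.traits,
        spec=spec, means=np.zeros(2), minus2ll=0.0, n_free=0, n_obs=0, df=0,
        converged=True,
    )
    assert np.allclose(fit.correlated_factors_solution().r_g, np.eye(2))


def test_cholesky_equivalent_to_its_correlated_factors_transform(study_data):
    """The transform is a reparameterization: component covariances rebuilt
    from (r, standardized) match the Cholesky ones to machine precision."""
    fit = ta.fit_multivariate(study_data, structure="cholesky", n_restarts=2)
    sol = fit.correlated_factors_solution()
    total = np.diag(fit.spec.within_twin_covariance(scaled=False))
    for comp in ("A", "E"):
        var = sol.standardized[comp] * total
        rebuilt = sol.correlations[comp] * np.sqrt(np.outer(var, var))
        assert np.allclose(
            rebuilt, fit.spec.component_covariance(comp), atol=1e-10
        )


def test_correlation_solution_entries_bounded(study_data):
    fit = ta.fit_multivariate(study_data, structure="cholesky", n_restarts=2)
    sol = fit.correlated_factors_solution()
    for M in sol.correlations.values():
        assert np.all(np.abs(M) <= 1.0 + 1e-10)
        assert np.allclose(np.diag(M), 1.0)


def test_pathway_decomposition_printed_formula():
    """λ = 0.90, a_F = 0.85, a_si = 0.22: genetic common share
    0.585225/0.633625 = 0.9236."""
    spec = GenerativeSpec(
        "common_pathway", ("A", "E"),
        {"factor": {"A": 0.85, "E": np.sqrt(1 - 0.85**2)},
         "loadings": np.array([0.90, 0.88]),
         "specific": {"A": np.array([0.22, 0.0]),
                      "E": np.array([0.38, 0.45])}},
    )
    from twinace.multivariate import MultivariateResults, pathway_decomposition

    fit = MultivariateResults(
        structure="common_pathway", components=("A", "E"), traits=spec.traits,
        spec=spec, means=np.zeros(2), minus2ll=0.0, n_free=0, n_obs=0, df=0,
        converged=True,
    )
    dec = pathway_decomposition(fit)
    assert dec.common_share["A"][0] == pytest.approx(0.585225 / 0.633625, abs=1e-10)
    assert dec.common_share["A"][1] == pytest.approx(1.0)  # no specific path
    assert dec.factor_heritability == pytest.approx(0.85**2)


def test_decomposition_shares_sum_to_one(study_data):
    fit = ta.fit_multivariate(study_data, structure="common_pathway", n_restarts=2)
    dec = fit.pathway_decomposition()
    for comp in ("A", "E"):
        total_pct = dec.pct_total[(comp, "common")] + dec.pct_total[(comp, "specific")]
        share_sum = dec.common_share[comp] + (1 - dec.common_share[comp])
        assert np.allclose(share_sum, 1.0, atol=1e-4)
        assert np.all(total_pct > 0)
    # total variance fully accounted for
    grand = sum(
        dec.pct_total[(c, kind)]
        for c in ("A", "E") for kind in ("common", "specific")
    )
    assert np.allclose(grand, 100.0, atol=1e-6)


def test_common_pathway_recovers_factor_heritability():
    """Mean factor-h² over replicated study-sized fits is within
    Monte-Carlo error (and < 0.03 bias) of the generating 0.7225."""
    gen = ta.study_mirror_spec()
    vals = []
    for i in range(25):
        d = ta.simulate(gen, 1135, 823, seed=600 + i)
        f = ta.fit_multivariate(d, structure="common_pathway", n_restarts=1)
        vals.append(f.pathway_decomposition().factor_heritability)
    vals = np.array(vals)
    assert abs(vals.mean() - 0.7225) < 0.03
    assert abs(vals.mean() - 0.7225) < 3 * vals.std(ddof=1) / np.sqrt(len(vals)) + 0.01


def test_decomposition_requires_common_pathway(study_data):
    fit = ta.fit_multivariate(study_data, structure="cholesky", n_restarts=1)
    with pytest.raises(ValueError):
        fit.pathway_decomposition()


def test_zero_component_variance_flagged():
    spec = GenerativeSpec(
        "cholesky", ("A", "E"),
        {"A": np.diag([0.7, 0.0]), "E": np.diag([0.5, 0.5])},
    )
    from twinace.multivariate import MultivariateResults

    fit = MultivariateResults(
        structure="cholesky", components=("A", "E"), traits=spec.traits,
        spec=spec, means=np.zeros(2), minus2ll=0.0, n_free=0, n_obs=0, df=0,
        converged=True,
    )
    with pytest.warns(UserWarning, match="zero A-component variance"):
        sol = fit.correlated_factors_solution()
    assert np.isnan(sol.r_g[0, 1])
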