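"""Multivariate biometric twin models fitted by FIML.

Three structures over k traits are supported, in decreasing order of freedom
(each is nested in the previous one):

``cholesky``
    each component's covariance is L Lᵀ with L lower-triangular — the
    saturated biometric structure; its transform is the correlated-factors
    solution (genetic / environmental correlation matrices).
``independent_pathway``
    per component, one common factor loading on every trait directly, plus a
    trait-specific factor.
``common_pathway``
    a single latent phenotypic factor, itself decomposed into A/C/E with
    a_F² + c_F² + e_F² = 1 (unit latent variance, the identification
    constraint), loading on traits through λ_i; plus trait-specific residual
    component factors.

Free-parameter counts for k = 4, AE: cholesky 2·10 + 4 means = 24,
independent pathway 2·(4+4) + 4 = 20, common pathway (2−1) + 4 + 2·4 + 4 =
17.  Fitted means are one per trait, shared across twins and zygosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import TwinDataset
from .exceptions import ConvergenceError, NotIdentifiedError
from .fiml import FIMLData, PENALTY, multistart_minimize, pair_covariance
from .generative import GenerativeSpec, _chol_lower, _validate_components

STRUCTURE_ORDER = ("cholesky", "independent_pathway", "common_pathway")


# ---------------------------------------------------------------------- #
# degrees of freedom
# ---------------------------------------------------------------------- #
def n_free_parameters(structure, components, k, specific_components=None) -> int:
    comps = _validate_components(components)
    nc = len(comps)
    if structure == "univariate":
        if k != 1:
            raise ValueError("univariate structure requires k = 1")
        return nc + 1
    if structure == "cholesky":
        return nc * (k * (k + 1) // 2) + k
    if structure == "independent_pathway":
        return nc * 2 * k + k
    if structure == "common_pathway":
        nspec = len(
            _validate_components(specific_components)
            if specific_components is not None
            else comps
        )
        return (nc - 1) + k + nspec * k + k
    raise ValueError(f"unknown structure: {structure}")


def model_degrees_of_freedom(
    structure, components, k, data: TwinDataset, traits=None,
    specific_components=None,
) -> int:
    """Observed-data degrees of freedom: non-missing phenotype observations
    minus free parameters (paths + means − identification constraints)."""
    traits = list(traits) if traits is not None else data.traits[:k]
    if len(traits) != k:
        raise ValueError("trait list length must equal k")
    n_obs = int((~np.isnan(data.phenotype_matrix(traits))).sum())
    return n_obs - n_free_parameters(structure, components, k, specific_components)


# ---------------------------------------------------------------------- #
# results containers
# ---------------------------------------------------------------------- #
@dataclass
class CorrelationSolution:
    """Correlated-factors transform of a multivariate fit: per-component
    correlation matrices and standardized variance components."""

    traits: tuple
    correlations: dict  # component -> k×k correlation matrix
    standardized: dict  # component -> per-trait variance share

    @property
    def r_g(self):
        return self.correlations.get("A")

    @property
    def r_c(self):
        return self.correlations.get("C")

    @property
    def r_d(self):
        return self.correlations.get("D")

    @property
    def r_e(self):
        return self.correlations.get("E")


@dataclass
class PathwayDecomposition:
    """Common- vs specific-factor variance shares of a common-pathway fit.

    Shares are per trait and per component: e.g. the genetic common share of
    trait i is (λ_i a_F)² / ((λ_i a_F)² + a_si²).  ``pct_total`` holds the
    percentage of each trait's total variance by source (component ×
    common/specific); ``factor_heritability`` is a_F² under the unit latent
    variance identification.
    """

    traits: tuple
    common_share: dict     # component -> (k,) share of component variance
    pct_total: dict        # (component, 'common'|'specific') -> (k,) % of total
    factor_heritability: float
    factor_components: dict  # component -> squared factor path

    def to_frame(self):
        import pandas as pd

        rows = {}
        for comp, share in self.common_share.items():
            rows[f"{comp}_common_share"] = share
            rows[f"{comp}_specific_share"] = 1.0 - share
        for (comp, kind), pct in self.pct_total.items():
            rows[f"pct_total_{comp}_{kind}"] = pct
        return pd.DataFrame(rows, index=list(self.traits))


@dataclass
class MultivariateResults:
    """Fitted multivariate biometric model."""

    structure: str
    components: tuple
    traits: tuple
    spec: GenerativeSpec
    means: np.ndarray
    minus2ll: float
    n_free: int
    n_obs: int
    df: int
    converged: bool
    specific_components: tuple = None
    _model_ref: object = field(default=None, repr=False)

    def implied_pair_covariance(self, zygosity: str) -> np.ndarray:
        return self.spec.implied_twin_covariance(zygosity)

    def correlated_factors_solution(self) -> CorrelationSolution:
        return correlated_factors_solution(self)

    def pathway_decomposition(self) -> PathwayDecomposition:
        return pathway_decomposition(self)

    def summary(self) -> str:
        std = self.spec.implied_standardized_components()
        lines = [
            f"{''.join(self.components)} {self.structure} model on "
            f"{len(self.traits)} traits",
            f"  -2lnL = {self.minus2ll:.4f}  (free parameters = "
            f"{self.n_free}, df = {self.df})",
        ]
        for i, t in enumerate(self.traits):
            parts = "  ".join(
                f"{c.lower()}²={std[c][i]:.3f}" for c in self.components
            )
            lines.append(f"  {t}: {parts}")
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
# model
# ---------------------------------------------------------------------- #
class MultivariateBiometricModel:
    """FIML fitter for Cholesky / independent-pathway / common-pathway
    structures over a set of traits."""

    def __init__(
        self,
        data: TwinDataset,
        traits=None,
        structure: str = "cholesky",
        components=("A", "E"),
        specific_components=None,
    ):
        if structure not in STRUCTURE_ORDER:
            raise ValueError(f"unknown structure: {structure}")
        self.structure = structure
        self.components = _validate_components(components)
        if structure == "common_pathway":
            self.specific_components = _validate_components(
                specific_components if specific_components is not None
                else self.components
            )
        else:
            self.specific_components = self.components
        self.traits = tuple(traits) if traits is not None else tuple(data.traits)
        self.k = len(self.traits)
        if self.k < 1:
            raise ValueError("at least one trait required")
        self.fimldata = FIMLData(data, self.traits)
        self._tril = np.tril_indices(self.k)
        self.n_free = n_free_parameters(
            structure, self.components, self.k,
            self.specific_components if structure == "common_pathway" else None,
        )

    # -------------------------- parameter packing --------------------- #
    def _unpack(self, x):
        """Parameter vector -> (component covariances dict, means, raw params)."""
        k = self.k
        pos = 0
        comp_covs = {}
        raw = {}
        if self.structure == "cholesky":
            m = k * (k + 1) // 2
            for c in self.components:
                L = np.zeros((k, k))
                L[self._tril] = x[pos:pos + m]
                pos += m
                comp_covs[c] = L @ L.T
                raw[c] = L
        elif self.structure == "independent_pathway":
            for c in self.components:
                f = x[pos:pos + k]
                s = x[pos + k:pos + 2 * k]
                pos += 2 * k
                comp_covs[c] = np.outer(f, f) + np.diag(s**2)
                raw[c] = {"common": f.copy(), "specific": s.copy()}
        else:  # common pathway
            free = [c for c in self.components if c != "E"]
            g = x[pos:pos + len(free)]
            pos += len(free)
            ssq = float(np.sum(g**2))
            if ssq >= 1.0 - 1e-10:
                return None, None, None  # infeasible factor paths
            fpaths = dict(zip(free, g))
            fpaths["E"] = np.sqrt(1.0 - ssq)
            lam = x[pos:pos + k]
            pos += k
            spec = {}
            for c in self.specific_components:
                spec[c] = x[pos:pos + k].copy()
                pos += k
            for c in self.components:
                s = spec.get(c, np.zeros(k))
                comp_covs[c] = fpaths[c] ** 2 * np.outer(lam, lam) + np.diag(s**2)
            raw = {"factor": fpaths, "loadings": lam.copy(), "specific": spec}
        means = x[pos:pos + k]
        return comp_covs, means, raw

    def minus2ll(self, x) -> float:
        comp_covs, means, _ = self._unpack(np.asarray(x, float))
        if comp_covs is None:
            return PENALTY
        mu = np.concatenate([means, means])
        sigma = {z: pair_covariance(comp_covs, z) for z in ("MZ", "DZ")}
        return self.fimldata.minus2ll(mu, sigma)

    # -------------------------- starting values ----------------------- #
    def _moment_component_covs(self):
        k = self.k
        Sw = {}
        Sx = {}
        mean = np.zeros(k)
        wsum = 0.0
        for zyg in ("MZ", "DZ"):
            pats = self.fimldata.patterns[zyg]
            full = [p for p in pats if len(p[0]) == 2 * k]
            if full:
                idx, n, s, S2 = full[0]
                m = s / n
                C = S2 / n - np.outer(m, m)
                Sw[zyg] = (C[:k, :k] + C[k:, k:]) / 2
                X = (C[:k, k:] + C[k:, :k].T) / 2
                Sx[zyg] = (X + X.T) / 2
                mean += n * (m[:k] + m[k:]) / 2
                wsum += n
            else:
                Sw[zyg] = np.eye(k)
                Sx[zyg] = 0.3 * np.eye(k)
        mean = mean / wsum if wsum else mean

        def psd(M, floor=1e-4):
            w, V = np.linalg.eigh((M + M.T) / 2)
            scale = max(np.abs(w).max(), 1.0)
            return (V * np.clip(w, floor * scale, None)) @ V.T

        Sw_p = (Sw["MZ"] + Sw["DZ"]) / 2
        covs = {}
        if "C" in self.components:
            covs["A"] = psd(2 * (Sx["MZ"] - Sx["DZ"]))
            covs["C"] = psd(2 * Sx["DZ"] - Sx["MZ"])
        elif "D" in self.components:
            covs["A"] = psd(4 * Sx["DZ"] - Sx["MZ"])
            covs["D"] = psd(2 * Sx["MZ"] - 4 * Sx["DZ"])
        elif "A" in self.components:
            covs["A"] = psd((Sx["MZ"] + 2 * Sx["DZ"]) / 2)
        rest = Sw_p - sum(covs.values()) if covs else Sw_p
        covs["E"] = psd(rest, floor=1e-3)
        return covs, mean, Sw_p

    def _starting_values(self):
        covs, mean, Sw = self._moment_component_covs()
        k = self.k
        parts = []
        if self.structure == "cholesky":
            for c in self.components:
                parts.append(_chol_lower(covs[c])[self._tril])
        elif self.structure == "independent_pathway":
            for c in self.components:
                w, V = np.linalg.eigh(covs[c])
                f = V[:, -1] * np.sqrt(max(w[-1], 1e-4))
                if f[0] < 0:
                    f = -f
                s2 = np.clip(np.diag(covs[c]) - f**2, 1e-4, None)
                parts.extend([f, np.sqrt(s2)])
        else:
            w, V = np.linalg.eigh(Sw)
            lam = V[:, -1] * np.sqrt(max(w[-1], 1e-4))
            if lam[0] < 0:
                lam = -lam
            lsq = np.sum(lam**2)
            free = [c for c in self.components if c != "E"]
            fsq = {}
            for c in free:
                num = float(lam @ covs[c] @ lam)
                fsq[c] = float(np.clip(num / max(lsq**2, 1e-8), 0.05, 0.9))
            total = sum(fsq.values())
            if total > 0.9:
                fsq = {c: v * 0.9 / total for c, v in fsq.items()}
            parts.append(np.sqrt([fsq[c] for c in free]))
            parts.append(lam)
            e_fsq = 1.0 - sum(fsq.values())
            fall = {**fsq, "E": e_fsq}
            for c in self.specific_components:
                s2 = np.clip(np.diag(covs[c]) - fall[c] * lam**2, 1e-4, None)
                parts.append(np.sqrt(s2))
        parts.append(mean)
        return np.concatenate(parts)

    # ------------------------------- fit ------------------------------- #
    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
    ) -> MultivariateResults:
        x0 = self._starting_values()
        rng = np.random.default_rng(seed)
        starts = [x0]
        npath = len(x0) - self.k
        for _ in range(max(n_restarts - 1, 0)):
            pert = x0.copy()
            pert[:npath] = pert[:npath] * rng.lognormal(0.0, 0.3, npath) \
                + rng.normal(0.0, 0.02, npath)
            starts.append(pert)
        res = multistart_minimize(self.minus2ll, starts, tol=tol, maxiter=5000)
        if res is None:
            raise ConvergenceError(
                f"{self.structure} fit failed to converge"
            )
        comp_covs, means, raw = self._unpack(res.x)
        spec = self._build_spec(raw, means)
        return MultivariateResults(
            structure=self.structure,
            components=self.components,
            traits=self.traits,
            spec=spec,
            means=np.asarray(means, float),
            minus2ll=float(res.fun),
            n_free=self.n_free,
            n_obs=self.fimldata.n_obs,
            df=self.fimldata.n_obs - self.n_free,
            converged=bool(res.success),
            specific_components=self.specific_components,
            _model_ref=self,
        )

    def _build_spec(self, raw, means) -> GenerativeSpec:
        """Canonicalize signs and wrap fitted paths in a GenerativeSpec."""
        if self.structure == "cholesky":
            params = {}
            for c, L in raw.items():
                L = L.copy()
                sign = np.sign(np.diag(L))
                sign[sign == 0] = 1.0
                params[c] = L * sign  # flip factor columns, L Lᵀ unchanged
        elif self.structure == "independent_pathway":
            params = {}
            for c, d in raw.items():
                f = d["common"]
                if f[0] < 0:
                    f = -f
                params[c] = {"common": f, "specific": np.abs(d["specific"])}
        else:
            lam = raw["loadings"]
            if lam[0] < 0:
                lam = -lam
            params = {
                "factor": {c: abs(float(v)) for c, v in raw["factor"].items()},
                "loadings": lam,
                "specific": {c: np.abs(v) for c, v in raw["specific"].items()},
            }
        return GenerativeSpec(
            structure=self.structure,
            components=self.components,
            params=params,
            traits=self.traits,
            means=np.asarray(means, float),
        )


def fit_multivariate(
    data: TwinDataset,
    traits=None,
    structure: str = "cholesky",
    components=("A", "E"),
    specific_components=None,
    **fit_kwargs,
) -> MultivariateResults:
    """Convenience wrapper: build the model and fit it."""
    return MultivariateBiometricModel(
        data, traits, structure, components, specific_components
    ).fit(**fit_kwargs)


# ---------------------------------------------------------------------- #
# transforms of fitted models
# ---------------------------------------------------------------------- #
def correlated_factors_solution(fit: MultivariateResults) -> CorrelationSolution:
    """Transform a (Cholesky) fit into component correlation matrices
    r_ij = X_ij / √(X_ii X_jj) with X = L Lᵀ, plus standardized variance
    components X_ii / total variance.  Undefined correlations (zero
    component variance for a trait) are flagged with NaN and a warning."""
    spec = fit.spec
    total = np.diag(spec.within_twin_covariance(scaled=False))
    correlations, standardized = {}, {}
    for c in fit.components:
        X = spec.component_covariance(c)
        d = np.diag(X).copy()
        standardized[c] = d / total
        zero = d <= 1e-12
        if zero.any():
            warnings.warn(
                f"zero {c}-component variance for trait(s) "
                f"{[fit.traits[i] for i in np.flatnonzero(zero)]}: "
                "correlation undefined"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            R = X / np.sqrt(np.outer(d, d))
        R[zero, :] = np.nan
        R[:, zero] = np.nan
        np.fill_diagonal(R, np.where(zero, np.nan, 1.0))
        correlations[c] = R
    return CorrelationSolution(fit.traits, correlations, standardized)


def pathway_decomposition(fit: MultivariateResults) -> PathwayDecomposition:
    """Split each trait's component variance into the part transmitted by
    the latent common factor and the trait-specific part (common-pathway
    fits only)."""
    if fit.structure != "common_pathway":
        raise ValueError("pathway decomposition requires a common-pathway fit")
    p = fit.spec.params
    lam = np.asarray(p["loadings"], float)
    k = lam.size
    total = np.diag(fit.spec.within_twin_covariance(scaled=False))
    common_share, pct_total = {}, {}
    for c in fit.components:
        fpath = float(p["factor"].get(c, 0.0))
        s = np.asarray(p.get("specific", {}).get(c, np.zeros(k)), float)
        common = (lam * fpath) ** 2
        comp_total = common + s**2
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(comp_total > 0, common / comp_total, np.nan)
        common_share[c] = share
        pct_total[(c, "common")] = 100.0 * common / total
        pct_total[(c, "specific")] = 100.0 * s**2 / total
    fsq = {c: float(p["factor"].get(c, 0.0)) ** 2 for c in fit.components}
    return PathwayDecomposition(
        traits=fit.traits,
        common_share=common_share,
        pct_total=pct_total,
        factor_heritability=fsq.get("A", 0.0) / sum(fsq.values()),
        factor_components=fsq,
    )
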