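"""Biometric generative models for twin pairs.

A :class:`GenerativeSpec` describes how latent additive-genetic (A), shared-
environmental (C), non-additive genetic (D) and non-shared environmental (E)
influences compose k observed traits, in one of four structures:

``univariate``
    scalar paths a, c (or d), e on a single trait.
``cholesky``
    one lower-triangular path matrix per component (the saturated
    multivariate biometric model; its transform is the correlated-factors
    solution).
``independent_pathway``
    per component, one common factor loading directly on every trait plus a
    trait-specific path.
``common_pathway``
    a single latent phenotypic factor with unit variance, decomposed into
    component paths (a_F, c_F, e_F with a_F² + c_F² + e_F² = 1), loading on
    traits through λ_i, plus trait-specific component paths.

Cross-twin correlations of the latent components are fixed by the biology of
twinning: A correlates 1.0 within MZ and 0.5 within DZ pairs, C is 1.0 for
both, D is 1.0 / 0.25, and E is uncorrelated across twins.  C and D cannot
be estimated together from twins reared together (the ACDE model is not
identified), so a spec may contain at most one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import qr

from .exceptions import NotIdentifiedError

#: cross-twin correlation of each latent component, by zygosity
CROSS_TWIN_CORR = {
    "A": {"MZ": 1.0, "DZ": 0.5},
    "C": {"MZ": 1.0, "DZ": 1.0},
    "D": {"MZ": 1.0, "DZ": 0.25},
    "E": {"MZ": 0.0, "DZ": 0.0},
}

STRUCTURES = ("univariate", "cholesky", "independent_pathway", "common_pathway")


def _validate_components(components):
    comps = tuple(components)
    if "E" not in comps:
        raise NotIdentifiedError("E must always be present")
    if "C" in comps and "D" in comps:
        raise NotIdentifiedError(
            "C and D cannot both be included: the ACDE model is not "
            "identified for twins reared together"
        )
    unknown = set(comps) - set("ACDE")
    if unknown:
        raise NotIdentifiedError(f"unknown component(s): {sorted(unknown)}")
    return tuple(c for c in "ACDE" if c in comps)


def _chol_lower(M: np.ndarray) -> np.ndarray:
    """Lower-triangular factor L with L Lᵀ = M, robust to PSD-singular M."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        w = np.clip(w, 0.0, None)
        B = V * np.sqrt(w)
        # LQ: Bᵀ = Q R  =>  B Bᵀ = Rᵀ R, L = Rᵀ lower-triangular
        _, R = qr(B.T, mode="economic")
        L = R.T
        # fix column signs so the diagonal is non-negative
        sign = np.sign(np.diag(L))
        sign[sign == 0] = 1.0
        return L * sign


@dataclass(frozen=True)
class GenerativeSpec:
    """A biometric twin model: structure, component set and path parameters.

    ``params`` layout by structure:

    - univariate: ``{"a": float, "c"/"d": float, "e": float}`` (keys for the
      components present).
    - cholesky: ``{comp: (k, k) lower-triangular path matrix}``.
    - independent_pathway: ``{comp: {"common": (k,), "specific": (k,)}}``.
    - common_pathway: ``{"factor": {comp: path}, "loadings": (k,),
      "specific": {comp: (k,)}}`` with factor paths normalized to unit
      latent variance.

    ``means``/``scales`` shift and scale the composed (unit-path) phenotypes
    per trait; ``beta_age``/``beta_sex`` add optional linear covariate
    effects (applied on the observed scale, centred so trait means stay at
    ``means``).
    """

    structure: str
    components: tuple
    params: dict
    traits: tuple = None
    means: np.ndarray = None
    scales: np.ndarray = None
    beta_age: np.ndarray = None
    beta_sex: np.ndarray = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure: {self.structure}")
        object.__setattr__(self, "components", _validate_components(self.components))
        k = self._infer_k()
        traits = self.traits or tuple(f"trait{i + 1}" for i in range(k))
        if len(traits) != k:
            raise ValueError("trait list length does not match parameters")
        object.__setattr__(self, "traits", tuple(traits))

        def vec(v, default):
            if v is None:
                return np.full(k, default, float)
            v = np.atleast_1d(np.asarray(v, float))
            if v.size == 1:
                v = np.repeat(v, k)
            if v.size != k:
                raise ValueError("per-trait vector has wrong length")
            return v

        object.__setattr__(self, "means", vec(self.means, 0.0))
        object.__setattr__(self, "scales", vec(self.scales, 1.0))
        if self.beta_age is not None:
            object.__setattr__(self, "beta_age", vec(self.beta_age, 0.0))
        if self.beta_sex is not None:
            object.__setattr__(self, "beta_sex", vec(self.beta_sex, 0.0))
        if self.structure == "common_pathway":
            fac = self.params["factor"]
            tot = sum(float(fac.get(c, 0.0)) ** 2 for c in "ACDE")
            if abs(tot - 1.0) > 1e-8:
                raise NotIdentifiedError(
                    "common-pathway factor paths must satisfy "
                    f"a_F² + c_F² + e_F² = 1 (got {tot:.6f})"
                )

    # ------------------------------------------------------------------ #
    def _infer_k(self) -> int:
        p = self.params
        if self.structure == "univariate":
            return 1
        if self.structure == "cholesky":
            return np.asarray(next(iter(p.values()))).shape[0]
        if self.structure == "independent_pathway":
            return np.asarray(next(iter(p.values()))["common"]).size
        return np.asarray(p["loadings"]).size

    @property
    def k(self) -> int:
        return len(self.traits)

    # ------------------------------------------------------------------ #
    # covariance algebra
    # ------------------------------------------------------------------ #
    def component_covariance(self, component: str) -> np.ndarray:
        """k×k within-twin covariance contributed by one component
        (on the unit-path scale, before trait scaling)."""
        if component not in self.components:
            return np.zeros((self.k, self.k))
        p = self.params
        if self.structure == "univariate":
            path = float(p[component.lower()])
            return np.array([[path**2]])
        if self.structure == "cholesky":
            L = np.asarray(p[component], float)
            return L @ L.T
        if self.structure == "independent_pathway":
            f = np.asarray(p[component]["common"], float)
            s = np.asarray(p[component].get("specific", np.zeros(self.k)), float)
            return np.outer(f, f) + np.diag(s**2)
        lam = np.asarray(p["loadings"], float)
        fpath = float(p["factor"].get(component, 0.0))
        s = np.asarray(p.get("specific", {}).get(component, np.zeros(self.k)), float)
        return fpath**2 * np.outer(lam, lam) + np.diag(s**2)

    def component_covariances(self) -> dict:
        return {c: self.component_covariance(c) for c in self.components}

    def within_twin_covariance(self, scaled: bool = True) -> np.ndarray:
        S = sum(self.component_covariances().values())
        if scaled:
            D = np.diag(self.scales)
            S = D @ S @ D
        return S

    def cross_twin_covariance(self, zygosity: str, scaled: bool = True) -> np.ndarray:
        S = sum(
            CROSS_TWIN_CORR[c][zygosity] * cov
            for c, cov in self.component_covariances().items()
        )
        S = np.atleast_2d(np.asarray(S, float))
        if scaled:
            D = np.diag(self.scales)
            S = D @ S @ D
        return S

    def implied_twin_covariance(self, zygosity: str) -> np.ndarray:
        """2k×2k model-implied covariance of (twin 1's traits, twin 2's)."""
        if zygosity not in ("MZ", "DZ"):
            raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
        Sw = self.within_twin_covariance()
        Sx = self.cross_twin_covariance(zygosity)
        return np.block([[Sw, Sx], [Sx.T, Sw]])

    # ------------------------------------------------------------------ #
    # implied summary quantities (used to calibrate and test simulators)
    # ------------------------------------------------------------------ #
    def implied_phenotypic_correlation(self) -> np.ndarray:
        S = self.within_twin_covariance()
        d = np.sqrt(np.diag(S))
        return S / np.outer(d, d)

    def implied_standardized_components(self) -> dict:
        """Per-trait variance proportions, e.g. ``{"A": array of h²}``."""
        total = np.diag(self.within_twin_covariance(scaled=False))
        return {
            c: np.diag(cov) / total for c, cov in self.component_covariances().items()
        }

    def implied_component_correlation(self, component: str) -> np.ndarray:
        cov = self.component_covariance(component)
        d = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            return cov / np.outer(d, d)

    def implied_intraclass_correlation(self, zygosity: str) -> np.ndarray:
        Sw = np.diag(self.within_twin_covariance())
        Sx = np.diag(self.cross_twin_covariance(zygosity))
        return Sx / Sw

    # ------------------------------------------------------------------ #
    # structure conversions (equivalence documented in the methods note)
    # ------------------------------------------------------------------ #
    def to_independent_pathway(self) -> "GenerativeSpec":
        """Common pathway -> independent pathway: common loadings become
        λ_i times the factor path of each component."""
        if self.structure == "independent_pathway":
            return self
        if self.structure != "common_pathway":
            raise ValueError("only a common-pathway spec converts to independent-pathway")
        lam = np.asarray(self.params["loadings"], float)
        spec = self.params.get("specific", {})
        params = {}
        for c in self.components:
            params[c] = {
                "common": lam * float(self.params["factor"].get(c, 0.0)),
                "specific": np.asarray(spec.get(c, np.zeros(self.k)), float),
            }
        return replace(self, structure="independent_pathway", params=params)

    def to_cholesky(self) -> "GenerativeSpec":
        """Any structure -> Cholesky paths factoring each component covariance."""
        if self.structure == "cholesky":
            return self
        params = {
            c: _chol_lower(self.component_covariance(c)) for c in self.components
        }
        return replace(self, structure="cholesky", params=params)


# ---------------------------------------------------------------------- #
# convenience constructors
# ---------------------------------------------------------------------- #
def univariate_spec(a=0.0, c=0.0, d=0.0, e=1.0, mean=0.0, scale=1.0,
                    beta_age=None, beta_sex=None, trait="trait1") -> GenerativeSpec:
    comps = ["E"]
    params = {"e": float(e)}
    if a:
        comps.append("A")
        params["a"] = float(a)
    if c:
        comps.append("C")
        params["c"] = float(c)
    if d:
        comps.append("D")
        params["d"] = float(d)
    return GenerativeSpec(
        "univariate", tuple(comps), params, traits=(trait,),
        means=[mean], scales=[scale], beta_age=beta_age, beta_sex=beta_sex,
    )


def implied_twin_covariance(spec: GenerativeSpec, zygosity: str) -> np.ndarray:
    """Functional alias for :meth:`GenerativeSpec.implied_twin_covariance`."""
    return spec.implied_twin_covariance(zygosity)
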