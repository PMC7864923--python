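"""Univariate biometric (ACE-family) twin models fitted by FIML.

A phenotype's variance is decomposed into additive genetic (A), shared
environmental (C) *or* non-additive genetic (D), and non-shared
environmental (E) parts by contrasting MZ and DZ twin resemblance.  Models
are parameterized by path coefficients (a, c/d, e), so variance components
a², c², e² are non-negative by construction; one grand mean is shared across
twins and zygosity groups.  The DE model is not offered: genetic dominance
in the absence of additive genetic variance is biologically implausible.

Confidence intervals for standardized components are profile-likelihood
bounds: the component value where -2lnL rises by the χ²₁ quantile above its
minimum while all other parameters are re-optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2 as chi2_dist

from .dataset import TwinDataset
from .exceptions import ConvergenceError, UnsupportedModelError
from .fiml import FIMLData, PENALTY, multistart_minimize
from .generative import CROSS_TWIN_CORR

MODEL_COMPONENTS = {
    "ACE": ("A", "C", "E"),
    "ADE": ("A", "D", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "E": ("E",),
}

CHI2_95 = float(chi2_dist.ppf(0.95, 1))  # 3.8415


@dataclass
class ProfileCI:
    """Profile-likelihood interval for a standardized variance component."""

    component: str
    lo: float
    hi: float
    lo_at_boundary: bool = False
    hi_at_boundary: bool = False
    level: float = 0.95


@dataclass
class UnivariateResults:
    """Fitted univariate biometric model."""

    model: str
    trait: str
    components: tuple
    paths: dict
    mean: float
    standardized: dict
    minus2ll: float
    n_free: int
    n_obs: int
    df: int
    converged: bool
    _model_ref: object = field(default=None, repr=False)

    def implied_pair_covariance(self, zygosity: str) -> np.ndarray:
        V = sum(p**2 for p in self.paths.values())
        cx = sum(
            CROSS_TWIN_CORR[c][zygosity] * p**2 for c, p in self.paths.items()
        )
        return np.array([[V, cx], [cx, V]])

    def profile_ci(self, component: str, level: float = 0.95) -> ProfileCI:
        return self._model_ref.profile_ci(self, component, level)

    def summary(self) -> str:
        comps = "  ".join(
            f"{c.lower()}²={self.standardized[c]:.3f}" for c in self.components
        )
        return (
            f"{self.model} model, trait '{self.trait}'\n"
            f"  standardized components: {comps}\n"
            f"  mean = {self.mean:.4f}\n"
            f"  -2lnL = {self.minus2ll:.4f}  (free parameters = {self.n_free}, "
            f"df = {self.df})"
        )


def _std_key(component: str) -> str:
    return component  # components are keyed by their letter throughout


def _component_from_alias(name: str) -> str:
    aliases = {"a2": "A", "c2": "C", "d2": "D", "e2": "E"}
    return aliases.get(name.lower(), name.upper())


class UnivariateBiometricModel:
    """FIML fitter for one trait under one ACE-family model label."""

    def __init__(self, data: TwinDataset, trait: str, model: str = "ACE"):
        model = model.upper()
        if model == "DE":
            raise UnsupportedModelError(
                "the DE model is not supported: dominance without additive "
                "genetic variance is biologically implausible"
            )
        if model not in MODEL_COMPONENTS:
            raise UnsupportedModelError(f"unknown model label: {model}")
        self.model = model
        self.trait = trait
        self.components = MODEL_COMPONENTS[model]
        self.fimldata = FIMLData(data, [trait])
        self._moments = _moment_summaries(data, trait)

    # ------------------------------------------------------------------ #
    def _sigma(self, variances: dict) -> dict:
        V = sum(variances.values())
        out = {}
        for zyg in ("MZ", "DZ"):
            cx = sum(
                CROSS_TWIN_CORR[c][zyg] * v for c, v in variances.items()
            )
            out[zyg] = np.array([[V, cx], [cx, V]])
        return out

    def minus2ll(self, paths, mean: float) -> float:
        """FIML -2lnL at given path coefficients and grand mean."""
        variances = {c: float(p) ** 2 for c, p in zip(self.components, paths)}
        mu = np.array([mean, mean])
        return self.fimldata.minus2ll(mu, self._sigma(variances))

    def _starting_values(self):
        V, rmz, rdz, mean = self._moments
        comp = dict.fromkeys(self.components, 0.0)
        if self.model == "ACE":
            comp["A"], comp["C"] = 2 * (rmz - rdz), 2 * rdz - rmz
            comp["E"] = 1 - rmz
        elif self.model == "ADE":
            comp["A"], comp["D"] = 4 * rdz - rmz, 2 * rmz - 4 * rdz
            comp["E"] = 1 - rmz
        elif self.model == "AE":
            comp["A"], comp["E"] = max(rmz, (rmz + 2 * rdz) / 2), 1 - rmz
        elif self.model == "CE":
            comp["C"], comp["E"] = max(rdz, rmz), 1 - rmz
        else:
            comp["E"] = 1.0
        vals = np.array([max(comp[c], 0.05) for c in self.components])
        vals = vals / vals.sum() * V
        return np.concatenate([np.sqrt(vals), [mean]])

    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
    ) -> UnivariateResults:
        x0 = self._starting_values()
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(n_restarts - 1, 0)):
            pert = x0.copy()
            pert[:-1] *= rng.lognormal(0.0, 0.4, size=len(x0) - 1)
            pert[-1] += rng.normal(0.0, 0.2) * max(abs(x0[-1]), 0.5)
            starts.append(pert)

        def objective(x):
            return self.minus2ll(x[:-1], x[-1])

        res = multistart_minimize(objective, starts, tol=tol)
        if res is None:
            raise ConvergenceError(
                f"{self.model} fit failed to converge for '{self.trait}'"
            )
        paths = {c: abs(float(p)) for c, p in zip(self.components, res.x[:-1])}
        total = sum(p**2 for p in paths.values())
        standardized = {c: p**2 / total for c, p in paths.items()}
        n_free = len(self.components) + 1
        return UnivariateResults(
            model=self.model,
            trait=self.trait,
            components=self.components,
            paths=paths,
            mean=float(res.x[-1]),
            standardized=standardized,
            minus2ll=float(res.fun),
            n_free=n_free,
            n_obs=self.fimldata.n_obs,
            df=self.fimldata.n_obs - n_free,
            converged=bool(res.success),
            _model_ref=self,
        )

    # ------------------------------------------------------------------ #
    # profile-likelihood confidence intervals
    # ------------------------------------------------------------------ #
    def _profiled_minus2ll(self, target: str, v: float, warm: dict) -> float:
        """Minimum -2lnL with the standardized `target` share fixed at v.

        ``warm`` carries the previous optimum (`x`, at share `v_last`) and a
        fixed anchor start (`x0`, the unconstrained fit); after a large jump
        in v the anchor is tried as well and the better optimum kept, since
        a stale warm start can strand the simplex in the wrong basin.
        """
        others = [c for c in self.components if c != target]
        anchor = warm.get("x0")
        if anchor is None:
            anchor = np.array([np.log(self._moments[0]), 0.0, self._moments[3]])
        starts = [warm["x"]] if warm.get("x") is not None else []
        v_last = warm.get("v")
        if not starts or v_last is None or abs(v - v_last) > 0.05:
            starts.append(anchor)
        n_other = len(others)

        def unpack(x):
            V = np.exp(x[0])
            variances = {target: v * V}
            rest = (1.0 - v) * V
            if n_other == 1:
                variances[others[0]] = rest
                mean = x[1]
            else:
                t = 1.0 / (1.0 + np.exp(-np.clip(x[1], -40.0, 40.0)))
                variances[others[0]] = t * rest
                variances[others[1]] = (1.0 - t) * rest
                mean = x[2]
            return variances, mean

        def objective(x):
            variances, mean = unpack(x)
            mu = np.array([mean, mean])
            return self.fimldata.minus2ll(mu, self._sigma(variances))

        npar = 2 if n_other == 1 else 3
        best = None
        for x0 in starts:
            res = minimize(
                objective,
                np.asarray(x0[:npar], float),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        warm["x"] = best.x
        warm["v"] = v
        return float(best.fun)

    def profile_ci(
        self, fit: UnivariateResults, component: str, level: float = 0.95
    ) -> ProfileCI:
        comp = _component_from_alias(component)
        if comp not in self.components:
            raise ValueError(
                f"component {comp} is not part of the {self.model} model"
            )
        if len(self.components) == 1:
            return ProfileCI(comp, 1.0, 1.0, True, True, level)
        v_hat = fit.standardized[comp]

        # anchor start from the fitted solution
        others = [c for c in self.components if c != comp]
        total = sum(p**2 for p in fit.paths.values())
        if len(others) == 1:
            anchor = np.array([np.log(total), fit.mean])
        else:
            o1 = fit.paths[others[0]] ** 2
            o2 = fit.paths[others[1]] ** 2
            t = np.clip(o1 / max(o1 + o2, 1e-12), 1e-6, 1 - 1e-6)
            anchor = np.array([np.log(total), np.log(t / (1 - t)), fit.mean])
        warm = {"x": anchor, "x0": anchor, "v": v_hat}
        warm0 = dict(warm)

        thr = fit.minus2ll + float(chi2_dist.ppf(level, 1))

        def g(v):
            return self._profiled_minus2ll(comp, float(v), warm) - thr

        lo, hi = profile_bounds(g, v_hat, lower=0.0, upper=1.0, warm_reset=lambda: warm.update(warm0))
        return ProfileCI(comp, lo[0], hi[0], lo[1], hi[1], level)


def profile_bounds(g, theta_hat, lower=0.0, upper=1.0, warm_reset=None):
    """Locate the two roots of ``g`` (profile -2lnL minus threshold) around
    ``theta_hat``; a side where no root exists inside the parameter space is
    clipped to the boundary and flagged.

    Returns ((lo, lo_clipped), (hi, hi_clipped)).
    """
    eps = 1e-9
    theta_hat = float(np.clip(theta_hat, lower, upper))

    # lower side
    if theta_hat - lower < 1e-7:
        lo = (lower, True)
    else:
        g_lo = g(lower + eps)
        lo = (
            (lower, True)
            if g_lo < 0
            else (float(brentq(g, lower + eps, theta_hat, xtol=1e-6)), False)
        )
    if warm_reset is not None:
        warm_reset()
    # upper side
    if upper - theta_hat < 1e-7:
        hi = (upper, True)
    else:
        g_hi = g(upper - eps)
        hi = (
            (upper, True)
            if g_hi < 0
            else (float(brentq(g, theta_hat, upper - eps, xtol=1e-6)), False)
        )
    return lo, hi


def fit_univariate(
    data: TwinDataset, trait: str, model: str = "ACE", **fit_kwargs
) -> UnivariateResults:
    """Convenience wrapper: build the model and fit it."""
    return UnivariateBiometricModel(data, trait, model).fit(**fit_kwargs)


def _moment_summaries(data: TwinDataset, trait: str):
    """(pooled variance, rMZ, rDZ, grand mean) from complete pairs, used for
    starting values only."""
    vals = []
    r = {}
    for zyg in ("MZ", "DZ"):
        P = data.trait_pairs(trait, zyg)
        P = P[~np.isnan(P).any(axis=1)]
        if len(P) >= 3:
            c = P - P.mean()
            s11, s22 = (c[:, 0] ** 2).sum(), (c[:, 1] ** 2).sum()
            s12 = (c[:, 0] * c[:, 1]).sum()
            r[zyg] = 2 * s12 / max(s11 + s22, 1e-12)
            vals.append(P.ravel())
        else:
            r[zyg] = 0.3 if zyg == "MZ" else 0.15
    allv = np.concatenate(vals) if vals else np.array([0.0, 1.0])
    V = float(np.var(allv)) or 1.0
    return V, float(np.clip(r["MZ"], -0.95, 0.95)), float(
        np.clip(r["DZ"], -0.95, 0.95)
    ), float(np.mean(allv))
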