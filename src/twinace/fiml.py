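"""Full-information maximum-likelihood machinery for twin models.

The FIML objective is the sum over families of -2 log multivariate-normal
density of each family's *observed* phenotype subvector under the
model-implied mean and the zygosity-appropriate implied covariance.
Families are grouped by (zygosity, missingness pattern) and summarized by
sufficient statistics (n, Σx, Σxxᵀ), so evaluating the objective costs one
Cholesky factorization per pattern instead of one per family.  With complete
data this reduces exactly to the closed-form two-group multivariate-normal
likelihood at the group sample moments.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .dataset import TwinDataset

LOG_2PI = float(np.log(2.0 * np.pi))
#: objective value returned when the implied covariance is not positive
#: definite at the evaluated parameters (a penalty, never a crash)
PENALTY = 1e12

ZYGOSITIES = ("MZ", "DZ")


class FIMLData:
    """Pattern-grouped sufficient statistics for a set of traits."""

    def __init__(self, data: TwinDataset, traits):
        self.traits = list(traits)
        self.k = len(self.traits)
        self.patterns = {z: [] for z in ZYGOSITIES}
        self.n_obs = 0
        self.n_families = {}
        for zyg in ZYGOSITIES:
            X = data.phenotype_matrix(self.traits, zyg)
            obs = ~np.isnan(X)
            any_obs = obs.any(axis=1)
            X, obs = X[any_obs], obs[any_obs]
            self.n_families[zyg] = int(any_obs.sum())
            self.n_obs += int(obs.sum())
            if len(X) == 0:
                continue
            # group rows sharing a missingness pattern
            codes = obs @ (1 << np.arange(obs.shape[1], dtype=np.int64))
            for code in np.unique(codes):
                rows = codes == code
                idx = np.flatnonzero(obs[np.argmax(rows)])
                Xo = X[np.ix_(rows, idx)]
                self.patterns[zyg].append(
                    (idx, len(Xo), Xo.sum(axis=0), Xo.T @ Xo)
                )

    @property
    def total_families(self) -> int:
        return sum(self.n_families.values())

    def complete(self) -> bool:
        return all(
            len(pats) <= 1 and all(len(p[0]) == 2 * self.k for p in pats)
            for pats in self.patterns.values()
        )

    def minus2ll(self, mu: np.ndarray, sigma: dict) -> float:
        """-2 log likelihood; ``mu`` is the 2k mean vector, ``sigma`` maps
        zygosity to a 2k×2k implied covariance.  Returns :data:`PENALTY`
        (plus a slope away from the infeasible region) when a required
        submatrix is not positive definite."""
        total = 0.0
        for zyg in ZYGOSITIES:
            S_full = sigma[zyg]
            for idx, n, s, S2 in self.patterns[zyg]:
                sub = S_full[np.ix_(idx, idx)]
                try:
                    cf = cho_factor(sub, lower=True, check_finite=False)
                except np.linalg.LinAlgError:
                    w = np.linalg.eigvalsh(sub)
                    return PENALTY * (1.0 + abs(float(w.min())))
                logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                m = len(idx)
                mu_s = mu[idx]
                M = S2 - np.outer(s, mu_s) - np.outer(mu_s, s) + n * np.outer(mu_s, mu_s)
                quad = float(np.trace(cho_solve(cf, M, check_finite=False)))
                total += n * (m * LOG_2PI + logdet) + quad
        return total

    def group_moments(self, zyg: str):
        """Sample mean and ML (1/n) covariance for a complete group."""
        (idx, n, s, S2), = self.patterns[zyg]
        mean = s / n
        cov = S2 / n - np.outer(mean, mean)
        return mean, cov, n


def multistart_minimize(objective, starts, bounds=None, tol=1e-8, maxiter=2000):
    """Run scipy L-BFGS-B from each start, keep the best optimum.

    Convergence uses ``ftol=tol`` (objective change between iterations).
    Returns the best ``OptimizeResult``; ``None`` if every start failed to
    produce a finite objective.
    """
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            np.asarray(x0, float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": maxiter},
        )
        if not np.isfinite(res.fun) or res.fun >= PENALTY:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def pair_covariance(comp_covs: dict, zygosity: str) -> np.ndarray:
    """Assemble the 2k×2k twin-pair covariance from per-component k×k
    covariance matrices."""
    from .generative import CROSS_TWIN_CORR

    k = next(iter(comp_covs.values())).shape[0]
    Sw = np.zeros((k, k))
    Sx = np.zeros((k, k))
    for c, cov in comp_covs.items():
        Sw += cov
        Sx += CROSS_TWIN_CORR[c][zygosity] * cov
    return np.block([[Sw, Sx], [Sx.T, Sw]])
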