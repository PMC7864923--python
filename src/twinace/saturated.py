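"""Saturated (baseline) twin model.

Per zygosity group, means (one per trait per twin position) and the full
2k×2k covariance are freely estimated; the resulting -2lnL is the baseline
every structured biometric model is tested against (likelihood-ratio χ²).
With complete data the ML solution is available in closed form at the group
sample moments; with missing cells it is found numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import TwinDataset
from .exceptions import ConvergenceError, InsufficientDataError
from .fiml import LOG_2PI, FIMLData, ZYGOSITIES, multistart_minimize


@dataclass
class SaturatedResults:
    """Fitted saturated model: group moments and baseline -2lnL."""

    traits: list
    minus2ll: float
    n_free: int
    n_obs: int
    df: int
    means: dict
    covariances: dict
    model = "saturated"

    def summary(self) -> str:
        lines = [
            f"Saturated twin model ({len(self.traits)} trait(s))",
            f"  -2lnL = {self.minus2ll:.4f}",
            f"  free parameters = {self.n_free}, df = {self.df}",
        ]
        return "\n".join(lines)


class SaturatedModel:
    """Unrestricted per-zygosity means/covariances, fitted by (FI)ML."""

    def __init__(self, data: TwinDataset, traits=None):
        traits = list(traits) if traits is not None else data.traits
        if isinstance(traits, str):
            traits = [traits]
        self.traits = traits
        self.k = len(traits)
        self.fimldata = FIMLData(data, traits)
        for zyg in ZYGOSITIES:
            if 0 < self.fimldata.n_families[zyg] < 3:
                raise InsufficientDataError(
                    f"fewer than 3 {zyg} pairs with data"
                )

    def fit(self, tol: float = 1e-8) -> SaturatedResults:
        p = 2 * self.k
        per_group = p + p * (p + 1) // 2
        n_free = sum(
            per_group for z in ZYGOSITIES if self.fimldata.n_families[z] > 0
        )
        means, covs = {}, {}
        total = 0.0
        for zyg in ZYGOSITIES:
            if self.fimldata.n_families[zyg] == 0:
                continue
            pats = self.fimldata.patterns[zyg]
            if len(pats) == 1 and len(pats[0][0]) == p:
                mean, cov, n = self.fimldata.group_moments(zyg)
                sign, logdet = np.linalg.slogdet(cov)
                if sign <= 0:
                    raise InsufficientDataError(
                        f"singular {zyg} sample covariance"
                    )
                total += n * (p * LOG_2PI + logdet + p)
            else:
                mean, cov, m2ll = self._fit_group(zyg, tol)
                total += m2ll
            means[zyg], covs[zyg] = mean, cov
        return SaturatedResults(
            traits=self.traits,
            minus2ll=float(total),
            n_free=n_free,
            n_obs=self.fimldata.n_obs,
            df=self.fimldata.n_obs - n_free,
            means=means,
            covariances=covs,
        )

    # numeric path for incomplete groups: optimize mean + Cholesky factor
    def _fit_group(self, zyg, tol):
        p = 2 * self.k
        tril = np.tril_indices(p)
        diag_pos = np.where(tril[0] == tril[1])[0]

        # start from available-case moments
        pats = self.fimldata.patterns[zyg]
        mu0 = np.zeros(p)
        var0 = np.ones(p)
        cnt = np.zeros(p)
        for idx, n, s, S2 in pats:
            mu0[idx] += s
            cnt[idx] += n
            var0[idx] += np.diag(S2)
        mu0 = np.where(cnt > 0, mu0 / np.maximum(cnt, 1), 0.0)
        var0 = np.where(cnt > 0, var0 / np.maximum(cnt, 1) - mu0**2, 1.0)
        var0 = np.clip(var0, 1e-3, None)
        L0 = np.diag(np.sqrt(var0))
        x0 = np.concatenate([mu0, L0[tril]])
        x0[p + diag_pos] = np.log(np.sqrt(var0))  # log-diagonal

        def unpack(x):
            mu = x[:p]
            Lv = x[p:].copy()
            Lv[diag_pos] = np.exp(Lv[diag_pos])
            L = np.zeros((p, p))
            L[tril] = Lv
            return mu, L @ L.T

        sub = FIMLData.__new__(FIMLData)
        sub.traits, sub.k = self.traits, self.k
        sub.patterns = {zyg: pats, ("DZ" if zyg == "MZ" else "MZ"): []}
        sub.n_obs = sum(len(i) * 0 + n * len(i) for i, n, _, _ in pats)
        sub.n_families = {zyg: self.fimldata.n_families[zyg]}

        def objective(x):
            mu, S = unpack(x)
            return sub.minus2ll(mu, {zyg: S, ("DZ" if zyg == "MZ" else "MZ"): S})

        res = multistart_minimize(objective, [x0], tol=tol, maxiter=5000)
        if res is None:
            raise ConvergenceError(f"saturated fit failed for {zyg} group")
        mu, S = unpack(res.x)
        return mu, S, float(res.fun)
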