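"""One-factor confirmatory factor analysis with ML fit indices.

Fits Σ(θ) = λλᵀ + Ψ (Ψ diagonal) to a correlation matrix by minimizing the
ML discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − k; χ² = (n−1)·F.  Fit indices
follow the conventional definitions:

    CFI   = 1 − max(χ²_m − df_m, 0) / max(χ²_b − df_b, χ²_m − df_m, 0)
    RMSEA = √( max(χ²_m − df_m, 0) / (df_m · (n−1)) )
    SRMR  = root mean square of residual correlations (lower triangle with
            diagonal)

with the independence model (free variances only) as the CFI baseline.
The first loading is constrained positive (sign convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .dataset import TwinDataset
from .exceptions import ConditioningError, InsufficientDataError


@dataclass
class CFAResults:
    """One-factor CFA fit: loadings, χ² ladder and fit indices."""

    traits: tuple
    loadings: np.ndarray
    uniquenesses: np.ndarray
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    rmsea: float
    srmr: float
    n: int

    def summary(self) -> str:
        lines = [f"One-factor CFA (n = {self.n})"]
        for t, l in zip(self.traits, self.loadings):
            lines.append(f"  {t}: loading = {l:.3f}")
        lines.append(
            f"  chi2({self.df}) = {self.chi2:.3f}   CFI = {self.cfi:.3f}   "
            f"RMSEA = {self.rmsea:.3f}   SRMR = {self.srmr:.4f}"
        )
        return "\n".join(lines)


class OneFactorCFA:
    """Single-factor ML confirmatory factor model on k ≥ 3 standardized
    traits, from a correlation matrix or from one randomly selected twin
    per family."""

    def __init__(self, corr: np.ndarray, n: int, traits=None):
        S = np.asarray(corr, float)
        k = S.shape[0]
        if k < 3:
            raise InsufficientDataError("one-factor CFA needs at least 3 traits")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("input matrix must be symmetric")
        w = np.linalg.eigvalsh(S)
        if w.min() <= 1e-10:
            raise ConditioningError(
                f"input matrix is not positive definite "
                f"(smallest eigenvalue {w.min():.3e})",
                smallest_eigenvalue=float(w.min()),
            )
        self.S = S
        self.n = int(n)
        self.k = k
        self.traits = tuple(traits) if traits is not None else tuple(
            f"trait{i + 1}" for i in range(k)
        )

    @classmethod
    def from_dataset(cls, data: TwinDataset, seed: int = 0) -> "OneFactorCFA":
        """Build from one randomly selected twin per family (seeded), to
        avoid the within-pair dependence of twin data."""
        rng = np.random.default_rng(seed)
        pick = rng.integers(1, 3, size=data.n_families)
        frame = data.frame
        cols = {}
        for t in data.traits:
            v1 = frame[t + "1"].to_numpy(float)
            v2 = frame[t + "2"].to_numpy(float)
            cols[t] = np.where(pick == 1, v1, v2)
        import pandas as pd

        ind = pd.DataFrame(cols).dropna()
        S = np.corrcoef(ind.to_numpy().T)
        return cls(S, n=len(ind), traits=data.traits)

    # ------------------------------------------------------------------ #
    def _discrepancy(self, lam, psi):
        Sigma = np.outer(lam, lam) + np.diag(psi)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10
        _, logdet_s = np.linalg.slogdet(self.S)
        return (
            logdet
            + float(np.trace(np.linalg.solve(Sigma, self.S)))
            - logdet_s
            - self.k
        )

    def fit(self, tol: float = 1e-10) -> CFAResults:
        k, n, S = self.k, self.n, self.S
        w, V = np.linalg.eigh(S)
        lam0 = V[:, -1] * np.sqrt(max(w[-1] - 1.0, 0.25))
        if lam0[0] < 0:
            lam0 = -lam0
        psi0 = np.clip(np.diag(S) - lam0**2, 0.05, None)
        x0 = np.concatenate([lam0, np.log(psi0)])

        def objective(x):
            return self._discrepancy(x[:k], np.exp(x[k:]))

        res = minimize(
            objective, x0, method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 5000},
        )
        lam = res.x[:k]
        if lam[0] < 0:
            lam = -lam
        psi = np.exp(res.x[k:])

        F = max(float(res.fun), 0.0)
        chi2 = (n - 1) * F
        df = k * (k + 1) // 2 - 2 * k
        # independence baseline: free variances, zero covariances
        _, logdet_s = np.linalg.slogdet(S)
        F_b = float(np.log(np.diag(S)).sum() - logdet_s)
        chi2_b = (n - 1) * F_b
        df_b = k * (k - 1) // 2

        excess_m = max(chi2 - df, 0.0)
        excess_b = max(chi2_b - df_b, excess_m, 0.0)
        cfi = 1.0 - (excess_m / excess_b if excess_b > 0 else 0.0)
        rmsea = float(np.sqrt(excess_m / (df * (n - 1)))) if df > 0 else 0.0
        Sigma = np.outer(lam, lam) + np.diag(psi)
        resid = S - Sigma
        tril = np.tril_indices(k)
        srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))
        return CFAResults(
            traits=self.traits,
            loadings=lam,
            uniquenesses=psi,
            chi2=float(chi2),
            df=df,
            baseline_chi2=float(chi2_b),
            baseline_df=df_b,
            cfi=float(cfi),
            rmsea=rmsea,
            srmr=srmr,
            n=n,
        )


def fit_single_factor_cfa(corr_or_data, n: int = None, seed: int = 0) -> CFAResults:
    """Fit a one-factor CFA from a correlation matrix (+ n) or from a
    TwinDataset (one twin per family, seeded selection)."""
    if isinstance(corr_or_data, TwinDataset):
        return OneFactorCFA.from_dataset(corr_or_data, seed=seed).fit()
    if n is None:
        raise ValueError("n is required with a correlation-matrix input")
    return OneFactorCFA(corr_or_data, n).fit()
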