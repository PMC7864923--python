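"""Likelihood-ratio testing and information-criterion model selection.

Every structured biometric model is referred to the saturated baseline:
χ² = (-2lnL of the model) − (-2lnL of the saturated model), a
likelihood-ratio goodness-of-fit test.  Nested structured models are
compared by Δχ² with Δdf equal to their df difference, against a plain χ²
reference (no boundary mixture correction).  Information criteria follow
the χ²-based convention

    AIC = χ² − 2·df        BIC = χ² − df·ln(n_units)

with n_units = the number of families (twin pairs), and BIC is the primary
selection criterion; ties break toward the more parsimonious model (larger
df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .exceptions import ConvergenceError


def likelihood_ratio_chi2(model_fit, saturated_fit):
    """(χ², model df, p vs saturated) for a structured fit against the
    saturated baseline.  A materially negative χ² signals a bad optimum."""
    chi2 = model_fit.minus2ll - saturated_fit.minus2ll
    if chi2 < -1e-6:
        raise ConvergenceError(
            f"negative likelihood-ratio chi-square ({chi2:.3g}): the "
            f"{getattr(model_fit, 'model', model_fit)} optimum is worse than "
            "the saturated baseline",
            best_value=model_fit.minus2ll,
        )
    chi2 = max(chi2, 0.0)
    ddf = model_fit.df - saturated_fit.df
    p = float(chi2_dist.sf(chi2, ddf)) if ddf > 0 else np.nan
    return float(chi2), int(model_fit.df), p


def delta_chi2(fit, reference_fit):
    """Δχ² test between two nested structured fits (fit nested in
    reference)."""
    d = fit.minus2ll - reference_fit.minus2ll
    if d < -1e-6:
        raise ConvergenceError(
            f"negative delta chi-square ({d:.3g}) between nested fits",
            best_value=fit.minus2ll,
        )
    d = max(d, 0.0)
    ddf = fit.df - reference_fit.df
    p = float(chi2_dist.sf(d, ddf)) if ddf > 0 else np.nan
    return float(d), int(ddf), p


def information_criteria(chi2: float, df: int, n_units: int):
    """AIC = χ² − 2df; BIC = χ² − df·ln(n_units), n_units = families."""
    if df < 0 or n_units < 1:
        raise ValueError("df must be >= 0 and n_units >= 1")
    return float(chi2 - 2.0 * df), float(chi2 - df * np.log(n_units))


@dataclass
class ComparisonRow:
    model: str
    chi2: float
    df: int
    dchi2: float
    ddf: float
    p: float
    aic: float
    bic: float


class ComparisonTable:
    """Model-comparison ladder: per-model χ², df, Δχ² (vs the first, fullest
    model), p, AIC and BIC."""

    def __init__(self, rows, n_units: int, reference: str = None):
        self.rows = list(rows)
        self.n_units = n_units
        self.reference = reference or (self.rows[0].model if self.rows else None)

    @classmethod
    def from_fits(cls, fits, saturated_fit, n_units: int) -> "ComparisonTable":
        """`fits` ordered from fullest to most restricted; Δ columns compare
        each fit to the first."""
        rows = []
        ref = fits[0]
        for i, f in enumerate(fits):
            chi2, df, _ = likelihood_ratio_chi2(f, saturated_fit)
            if i == 0:
                dchi2 = ddf = p = np.nan
            else:
                dchi2, ddf, p = delta_chi2(f, ref)
            aic, bic = information_criteria(chi2, df, n_units)
            label = getattr(f, "model", None) or getattr(f, "structure")
            rows.append(ComparisonRow(label, chi2, df, dchi2, ddf, p, aic, bic))
        return cls(rows, n_units)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.model,
                    "chi2": r.chi2,
                    "df": r.df,
                    "dchi2": r.dchi2,
                    "ddf": r.ddf,
                    "p": r.p,
                    "AIC": r.aic,
                    "BIC": r.bic,
                }
                for r in self.rows
            ]
        )

    def write_csv(self, path) -> None:
        """Write with reporting conventions: 2-decimal criteria, p-values
        below 0.01 printed as '< 0.01'."""
        f = self.to_frame().copy()
        for col in ("chi2", "dchi2", "AIC", "BIC"):
            f[col] = f[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        f["p"] = f["p"].map(
            lambda v: ""
            if pd.isna(v)
            else ("< 0.01" if v < 0.01 else f"{v:.2f}")
        )
        f.to_csv(path, index=False)

    def select(self, criterion: str = "BIC") -> str:
        return select_model(self, criterion)


def select_model(table: ComparisonTable, criterion: str = "BIC") -> str:
    """Model with the minimal criterion; ties break toward parsimony
    (larger df)."""
    if not table.rows:
        raise ValueError("empty comparison table")
    key = {"BIC": lambda r: r.bic, "AIC": lambda r: r.aic}[criterion.upper()]
    best = min(table.rows, key=lambda r: (round(key(r), 10), -r.df))
    return best.model


def compare_univariate(
    data, trait, models=("ACE", "AE", "CE", "E"), n_units=None, **fit_kwargs
):
    """Fit the univariate ladder plus the saturated baseline and tabulate."""
    from .saturated import SaturatedModel
    from .univariate import UnivariateBiometricModel

    sat = SaturatedModel(data, [trait]).fit()
    fits = [
        UnivariateBiometricModel(data, trait, m).fit(**fit_kwargs) for m in models
    ]
    n_units = n_units or data.n_families
    return ComparisonTable.from_fits(fits, sat, n_units), fits, sat


def compare_multivariate(
    data,
    traits=None,
    structures=("cholesky", "independent_pathway", "common_pathway"),
    components=("A", "E"),
    n_units=None,
    **fit_kwargs,
):
    """Fit the multivariate ladder plus the saturated baseline and
    tabulate."""
    from .multivariate import MultivariateBiometricModel
    from .saturated import SaturatedModel

    traits = list(traits) if traits is not None else data.traits
    sat = SaturatedModel(data, traits).fit()
    fits = [
        MultivariateBiometricModel(data, traits, s, components).fit(**fit_kwargs)
        for s in structures
    ]
    n_units = n_units or data.n_families
    return ComparisonTable.from_fits(fits, sat, n_units), fits, sat
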