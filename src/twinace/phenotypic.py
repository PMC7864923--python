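"""Phenotypic descriptives, correlations and intraclass twin correlations.

All individual-level statistics pool both twins of every family.  Simple and
partial Pearson correlations carry Fisher-z confidence intervals with
effective n = number of individuals; intraclass correlations (ICCs) are
constrained-maximum-likelihood bivariate-normal correlations (means and
variances equal across twin order — the twin-literature convention) with
Fisher-z intervals on the number of pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TwinDataset
from .exceptions import InsufficientDataError
from .preprocess import residualize_covariates


@dataclass
class CorrelationReport:
    """One pairwise correlation with its 95% CI."""

    trait_a: str
    trait_b: str
    r: float
    lo: float
    hi: float
    flavor: str  # 'simple' | 'partial'
    n: int


@dataclass
class ICCReport:
    trait: str
    zygosity: str
    r: float
    lo: float
    hi: float
    n_pairs: int


def _fisher_ci(r, n, level=0.95):
    from scipy.stats import norm

    if not np.isfinite(r) or n <= 3 or abs(r) >= 1:
        return (np.nan, np.nan) if abs(r) < 1 else (r, r)
    z = np.arctanh(r)
    half = norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def descriptives(data: TwinDataset) -> pd.DataFrame:
    """Individual-level mean and SD (n−1 denominator) per trait, pooling
    both twins; all-missing traits report NaN."""
    ind = data.individuals()
    rows = []
    for t in data.traits:
        v = ind[t].dropna()
        rows.append(
            {
                "trait": t,
                "n": len(v),
                "mean": v.mean() if len(v) else np.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else (0.0 if len(v) == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def correlation_matrix(
    data: TwinDataset, partial_on=(), level: float = 0.95
):
    """Pairwise Pearson correlations at the individual level.

    With ``partial_on`` nonempty, traits are first residualized on the named
    covariates (age/sex) and the correlations of the residuals are reported
    as partial correlations.  Returns (k×k DataFrame, list of
    CorrelationReport).  Zero-variance traits yield NaN entries flagged by a
    warning.
    """
    partial_on = tuple(partial_on)
    if partial_on:
        data, _ = residualize_covariates(data, covariates=partial_on)
        flavor = "partial"
    else:
        flavor = "simple"
    ind = data.individuals()
    k = len(data.traits)
    R = pd.DataFrame(np.eye(k), index=data.traits, columns=data.traits)
    reports = []
    for a, b in itertools.combinations(data.traits, 2):
        sub = ind[[a, b]].dropna()
        n = len(sub)
        if n < 4:
            raise InsufficientDataError(
                f"fewer than 4 complete individuals for ({a}, {b})"
            )
        sa, sb = sub[a].std(), sub[b].std()
        if sa < 1e-12 or sb < 1e-12:
            warnings.warn(f"zero variance in ({a}, {b}): correlation undefined")
            r = np.nan
        else:
            r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        lo, hi = _fisher_ci(r, n, level)
        R.loc[a, b] = R.loc[b, a] = r
        reports.append(CorrelationReport(a, b, r, lo, hi, flavor, n))
    return R, reports


def intraclass_correlation(
    data: TwinDataset, trait: str, zygosity: str, level: float = 0.95
) -> ICCReport:
    """Maximum-likelihood intraclass correlation for one zygosity group.

    Under a bivariate normal with means and variances constrained equal
    across twin order, the ML estimate is r̂ = 2·s₁₂ / (s₁₁ + s₂₂) with all
    sums of squares taken about the grand mean — which also makes the
    estimator exactly invariant to swapping twins within pairs.
    """
    P = data.trait_pairs(trait, zygosity)
    P = P[~np.isnan(P).any(axis=1)]
    n = len(P)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 complete {zygosity} pairs for '{trait}'"
        )
    grand = P.mean()
    c = P - grand
    s11 = float((c[:, 0] ** 2).sum())
    s22 = float((c[:, 1] ** 2).sum())
    s12 = float((c[:, 0] * c[:, 1]).sum())
    r = 2.0 * s12 / (s11 + s22)
    lo, hi = _fisher_ci(r, n, level)
    return ICCReport(trait, zygosity, float(r), lo, hi, n)


def table1_report(data: TwinDataset, partial_on=("age", "sex")) -> pd.DataFrame:
    """Descriptives + correlation block (simple below / partial above the
    diagonal) + MZ/DZ intraclass correlations, one row per trait."""
    desc = descriptives(data)
    R_simple, _ = correlation_matrix(data)
    R_partial, _ = correlation_matrix(data, partial_on=partial_on)
    out = desc.copy()
    traits = list(data.traits)
    for i2, t2 in enumerate(traits):
        col = []
        for i1, t1 in enumerate(traits):
            if i1 > i2:
                col.append(R_simple.loc[t1, t2])
            elif i1 < i2:
                col.append(R_partial.loc[t1, t2])
            else:
                col.append(np.nan)
        out[t2] = col
    for zyg in ("MZ", "DZ"):
        out[f"icc_{zyg}"] = [
            intraclass_correlation(data, t, zyg).r for t in data.traits
        ]
    return out
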