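"""Covariate adjustment of twin phenotypes.

Biometric modelling conventionally removes fixed effects of age and sex
before variance decomposition: each phenotype is replaced by its residual
from an individual-level OLS regression (both twins pooled) on the chosen
covariates.  Pairing is preserved, so within-family covariance structure is
untouched apart from the removed covariate component.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .dataset import TwinDataset
from .exceptions import SingularDesignError


def _design(age, sex, covariates, interaction, quadratic_age):
    cols = [np.ones_like(age)]
    if "age" in covariates:
        cols.append(age)
        if quadratic_age:
            cols.append(age**2)
    if "sex" in covariates:
        cols.append(sex)
    if interaction and "age" in covariates and "sex" in covariates:
        cols.append(age * sex)
    return np.column_stack(cols)


def residualize_covariates(
    data: TwinDataset,
    covariates=("age", "sex"),
    interaction: bool = False,
    quadratic_age: bool = False,
):
    """Replace each phenotype by OLS residuals on age and/or sex.

    The regression pools both twins of every family (non-independence within
    pairs is ignored for these point estimates; no inference is drawn from
    the regression itself).  Sex is coded 0/1, age in years, main effects
    only by default; an age x sex interaction and quadratic age are exposed
    as options.

    Returns
    -------
    (TwinDataset, dict)
        The residualized dataset and, per trait, the Pearson correlation of
        residuals with original scores (a diagnostic for how much variance
        the covariates removed).
    """
    covariates = tuple(covariates)
    if not set(covariates) <= {"age", "sex"}:
        raise ValueError(f"unsupported covariates: {covariates}")
    frame = data.frame
    n = len(frame)
    # individual-level stacks: twin 1 then twin 2
    age = np.concatenate([frame["age"].to_numpy(float)] * 2)
    sex = np.concatenate(
        [frame["sex1"].to_numpy(float), frame["sex2"].to_numpy(float)]
    )
    X_full = _design(age, sex, covariates, interaction, quadratic_age)
    if X_full.shape[1] > 1:
        centered = X_full[:, 1:] - np.nanmean(X_full[:, 1:], axis=0)
        if np.any(np.nanstd(centered, axis=0) < 1e-12):
            raise SingularDesignError("constant covariate in residualization design")

    new_cols = {}
    diagnostics = {}
    for t in data.traits:
        y = np.concatenate(
            [frame[t + "1"].to_numpy(float), frame[t + "2"].to_numpy(float)]
        )
        obs = ~np.isnan(y)
        resid = np.full_like(y, np.nan)
        model = sm.OLS(y[obs], X_full[obs])
        try:
            res = model.fit()
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise SingularDesignError(str(err)) from err
        if np.linalg.matrix_rank(X_full[obs]) < X_full.shape[1]:
            raise SingularDesignError("singular covariate design")
        resid[obs] = res.resid
        r = np.corrcoef(y[obs], resid[obs])[0, 1] if obs.sum() > 2 else np.nan
        diagnostics[t] = float(r)
        new_cols[t + "1"] = resid[:n]
        new_cols[t + "2"] = resid[n:]
    return data.with_phenotypes(new_cols), diagnostics
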