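"""Demographic residualization of behavior scores and methylation values.

Behavior (VABS) raw domain scores are regressed on age, age squared and
gender and replaced by standardized residuals (Z-scores); methylation
beta-values at candidate probes are regressed on age and gender and replaced
by standardized residuals (z-values).  The asymmetry — a quadratic age term
for behavior, linear for methylation — is deliberate and mirrors how the
two kinds of measurements were adjusted in the emulated analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ewaskit.simulate import VABS_DOMAINS


def _design(covariate_matrix: np.ndarray) -> np.ndarray:
    n = covariate_matrix.shape[0]
    X = np.column_stack([np.ones(n), covariate_matrix])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name offending columns by index for the caller
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariate design (columns {bad})")
    return X


def residualize(y, covariate_matrix) -> np.ndarray:
    """Standardized OLS residuals of ``y`` on covariates (with intercept).

    Residuals are divided by their sample SD (ddof=1): the output has mean 0
    and SD 1 and is exactly orthogonal to every covariate column.  A zero
    residual variance (constant ``y``) yields an all-zero vector with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    if len(y) <= C.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    if np.any(np.isnan(y)):
        raise ValueError("y must not contain missing values")
    X = _design(C)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    if sd == 0:
        warnings.warn("zero residual variance; returning all-zero residuals",
                      stacklevel=2)
        return np.zeros_like(y)
    return resid / sd


def vabs_covariates(samples: pd.DataFrame, age_column: str = "age_vabs_months") -> np.ndarray:
    """Age, (centered) age squared and gender for the behavior adjustment."""
    age = samples[age_column].to_numpy(dtype=float)
    age_c = age - age.mean()  # centering reduces collinearity; residuals unchanged
    return np.column_stack([age_c, age_c**2, samples["gender"].to_numpy(dtype=float)])


def adjust_vabs(vabs_raw: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Demographics-adjusted behavior Z-scores, one column per domain.

    Each domain's raw scores are regressed on age (at assessment), age
    squared and gender; samples with a missing raw score are dropped for
    that domain (their Z is NaN).
    """
    domains = [d for d in VABS_DOMAINS if d in vabs_raw.columns] or list(vabs_raw.columns)
    out = pd.DataFrame(np.nan, index=vabs_raw.index, columns=domains)
    for d in domains:
        ok = vabs_raw[d].notna()
        cov = vabs_covariates(samples.loc[vabs_raw.index[ok]])
        out.loc[ok, d] = residualize(vabs_raw.loc[ok, d].to_numpy(), cov)
    return out


def adjust_betas(
    beta_at_dmes: pd.DataFrame, samples: pd.DataFrame, age_column: str = "age_months"
) -> pd.DataFrame:
    """Demographics-adjusted methylation z-values (probes x samples).

    Each probe's beta row is regressed on age (at blood draw) and gender;
    rows are standardized residuals with mean 0 and SD 1.
    """
    cols = beta_at_dmes.columns
    age = samples.loc[cols, "age_months" if age_column == "age_months" else age_column]
    C = np.column_stack(
        [age.to_numpy(dtype=float), samples.loc[cols, "gender"].to_numpy(dtype=float)]
    )
    X = _design(C)
    Y = beta_at_dmes.to_numpy(dtype=float).T  # samples x probes
    if np.any(np.isnan(Y)):
        raise ValueError("beta matrix must not contain missing values")
    H, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ H
    sd = R.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("constant probes produce all-zero z-values", stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    Z = (R / sd).T
    Z[zero] = 0.0
    return pd.DataFrame(Z, index=beta_at_dmes.index, columns=cols)
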