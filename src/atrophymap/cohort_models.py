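"""Cohort-level association analyses.

Two complements to the voxelwise stage: a multiple regression of the
significant-region mean change on one brain factor plus demographics
(testing whether the voxelwise association survives adjustment for age,
gender, education, and ethnicity), and the Pearson correlation matrix of
the brain factors themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, StatisticsError
from .survival import encode_design


@dataclass
class RegressionFit:
    r_squared: float
    coefficients: pd.Series
    p_values: pd.Series
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise StatisticsError(f"R^2 out of range: {self.r_squared}")


def fit_multi_regression(
    outcome,
    terms: pd.DataFrame,
    categorical: tuple[str, ...] = ("ethnicity",),
) -> RegressionFit:
    """OLS with intercept of ``outcome`` on the named predictor columns.

    Categorical terms are dummy-coded exactly as in the survival models
    (most frequent level as reference).  Reports R-squared and two-sided
    per-term t-test p-values.  Rank-deficient designs raise with the
    collinear terms named.
    """
    y = np.asarray(outcome, dtype=float)
    X = encode_design(terms, list(terms.columns), categorical=categorical)
    n, k = X.shape
    if n <= k + 1:
        raise StatisticsError(f"need n > #terms + 1 ({k + 1}), got n = {n}")
    if X.isna().any().any() or np.isnan(y).any():
        raise StatisticsError("missing values present; no imputation is performed")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        pairs = [
            f"{X.columns[i]} ~ {X.columns[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ] or [c for c in X.columns if X[c].nunique() == 1]
        raise CollinearityError(f"rank-deficient design; collinear terms: {pairs}")
    fit = sm.OLS(y, Xc).fit()
    return RegressionFit(
        r_squared=float(fit.rsquared),
        coefficients=fit.params,
        p_values=fit.pvalues,
        n=n,
    )


def correlation_matrix(factors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the named factors.

    Requires >= 3 subjects and nonzero variance in every factor; the
    diagonal is exactly 1.
    """
    if len(factors) < 3:
        raise StatisticsError(f"need >= 3 subjects, got {len(factors)}")
    for col in factors.columns:
        if np.asarray(factors[col], dtype=float).std() == 0:
            raise StatisticsError(f"factor {col!r} has zero variance")
    arr = factors.astype(float).corr(method="pearson").to_numpy()
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=factors.columns, columns=factors.columns)
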