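"""Cox proportional-hazards models of conversion from normal cognition.

Each model contains the demographic covariates age, gender, education,
and ethnicity plus exactly one Z-scored brain factor (an ROI FA mean, a
significant-region mean change, a GM volume).  The brain factor's
contribution is assessed by a likelihood-ratio test of the full model
against the model without it; its hazard ratio is reported per unit
Z-score so effect sizes are comparable across factors, while age stays
per year.

Fits use the Efron approximation for tied event times (via lifelines).
Ethnicity enters as treatment-coded dummies with the most frequent
category as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .errors import CollinearityError, StatisticsError

DEMOGRAPHIC_COVARIATES = ["age", "gender", "education", "ethnicity"]


@dataclass
class CoxFit:
    """Summary of one proportional-hazards model.

    ``summary`` holds per-term coefficient, hazard ratio with 95% Wald CI
    (on the log-HR scale), and Wald p-value; ``lr_statistic`` /
    ``lr_p_value`` are the likelihood-ratio chi-square (1 df) for
    dropping the brain factor.
    """

    brain_factor: str
    summary: pd.DataFrame
    lr_statistic: float
    lr_p_value: float
    n: int
    n_events: int
    log_likelihood_full: float
    log_likelihood_reduced: float

    @property
    def hazard_ratio(self) -> float:
        """HR of the brain factor per unit Z increase."""
        return float(self.summary.loc[self.brain_factor, "hazard_ratio"])

    @property
    def hazard_ratio_ci(self) -> tuple[float, float]:
        row = self.summary.loc[self.brain_factor]
        return float(row["hr_ci_lower"]), float(row["hr_ci_upper"])


def zscore(values) -> np.ndarray:
    """Standardize to the analysis cohort's mean and sample SD (ddof=1)."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise StatisticsError("cannot Z-score a constant vector")
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd


def encode_design(
    records: pd.DataFrame,
    columns: list[str],
    categorical: tuple[str, ...] = ("ethnicity",),
) -> pd.DataFrame:
    """Numeric design matrix: categorical columns become treatment-coded
    dummies with the most frequent level as reference."""
    out = {}
    for col in columns:
        if col in categorical and not pd.api.types.is_numeric_dtype(records[col]):
            series = records[col].astype(str)
            ref = series.value_counts().idxmax()
            for level in sorted(series.unique()):
                if level != ref:
                    out[f"{col}[{level}]"] = (series == level).astype(float)
        else:
            out[col] = pd.to_numeric(records[col]).astype(float)
    return pd.DataFrame(out, index=records.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    centered = arr - arr.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        corr = np.corrcoef(arr, rowvar=False)
        pairs = [
            f"{X.columns[i]} ~ {X.columns[j]}"
            for i in range(len(X.columns))
            for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {pairs or 'not a simple pair'}"
        )


def _fit_partial_likelihood(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise StatisticsError(f"Cox model failed to converge: {exc}") from exc
    return fitter

def fit_cox(
    records: pd.DataFrame,
    brain_factor: str,
    time_col: str = "time_years",
    event_col: str = "converted",
    covariates: list[str] | None = None,
    standardize_brain_factor: bool = True,
) -> CoxFit:
    """Proportional-hazards fit of conversion on demographics + one brain factor.

    The brain factor is Z-scored against this cohort (so its HR is per
    unit Z); records with missing values are rejected rather than
    imputed.  Efron tie handling.  The likelihood-ratio test compares
    the full model to the same model without the brain factor.
    """
    covariates = DEMOGRAPHIC_COVARIATES if covariates is None else covariates
    needed = [time_col, event_col, brain_factor, *covariates]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise StatisticsError(f"missing columns: {missing}")
    if records[needed].isna().any().any():
        raise StatisticsError("missing values present; no imputation is performed")
    events = records[event_col].astype(int)
    if events.sum() == 0:
        raise StatisticsError("no conversion events; hazard model not estimable")
    if not ((records[time_col] > 0).all()):
        raise StatisticsError("all times must be > 0")

    X = encode_design(records, [*covariates, brain_factor])
    if standardize_brain_factor:
        X[brain_factor] = zscore(X[brain_factor])
    _check_rank(X)

    df_full = X.copy()
    df_full[time_col] = records[time_col].to_numpy(dtype=float)
    df_full[event_col] = events.to_numpy()
    full = _fit_partial_likelihood(df_full, time_col, event_col)
    ll_full = float(full.log_likelihood_)
    if len(X.columns) > 1:
        reduced = _fit_partial_likelihood(
            df_full.drop(columns=[brain_factor]), time_col, event_col
        )
        ll_reduced = float(reduced.log_likelihood_)
    else:
        # covariate-free reduced model: its partial likelihood is the null
        # likelihood of the full fit
        lr_null = full.log_likelihood_ratio_test()
        ll_reduced = ll_full - float(lr_null.test_statistic) / 2.0
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    lr_p = float(stats.chi2.sf(lr, df=1))

    s = full.summary
    summary = pd.DataFrame(
        {
            "coefficient": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "hr_ci_lower": s["exp(coef) lower 95%"],
            "hr_ci_upper": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    return CoxFit(
        brain_factor=brain_factor,
        summary=summary,
        lr_statistic=lr,
        lr_p_value=lr_p,
        n=len(records),
        n_events=int(events.sum()),
        log_likelihood_full=ll_full,
        log_likelihood_reduced=ll_reduced,
    )
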