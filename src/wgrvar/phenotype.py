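"""Build the cross-sectional standardized log-SBP response.

From a longitudinal table (up to four visits per subject, possibly with
missing measurements) the first complete visit per subject is taken,
systolic blood pressure is log-transformed to control skewness and then
standardized (centered, unit sample variance), and the nongenetic
covariates recorded at that same visit — age, sex, smoking, blood
pressure medication — are assembled into the fixed-effect matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "COVARIATE_COLUMNS",
    "LogStandardizer",
    "select_first_visit",
    "log_standardize",
    "build_covariate_matrix",
    "prepare_cohort",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "smoke", "bpmed")


class LogStandardizer(TransformerMixin, BaseEstimator):
    """log-transform then scale to zero mean, unit sample variance (ddof=1).

    Fitted attributes ``mean_`` and ``sd_`` record the log-scale moments
    so the transform can be inverted back to the measurement scale.
    """

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float64).ravel()
        if x.size < 2:
            raise ValueError("need at least 2 values to standardize")
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise ValueError("values must be positive and finite")
        lx = np.log(x)
        self.mean_ = float(lx.mean())
        self.sd_ = float(lx.std(ddof=1))
        if self.sd_ == 0.0:
            raise ValueError("zero variance: all values identical")
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=np.float64)
        if np.any(x <= 0):
            raise ValueError("values must be positive")
        return (np.log(x) - self.mean_) / self.sd_

    def inverse_transform(self, X):
        return np.exp(np.asarray(X, dtype=np.float64) * self.sd_ + self.mean_)


def log_standardize(sbp):
    """Standardized log values plus the (mean, sd) transform record."""
    est = LogStandardizer().fit(sbp)
    return est.transform(sbp), {"log_mean": est.mean_, "log_sd": est.sd_}


def select_first_visit(long_df: pd.DataFrame, n_visits: int = 4) -> pd.DataFrame:
    """One record per subject: the lowest-numbered complete visit.

    A visit is complete when SBP and all four covariates are non-missing.
    Subjects with no complete visit are dropped (and counted in the log).
    Duplicate (subject, visit) rows are an error.
    """
    required = ["subject_id", "visit", "sbp", *COVARIATE_COLUMNS]
    missing_cols = [c for c in required if c not in long_df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    if long_df.duplicated(["subject_id", "visit"]).any():
        raise ValueError("duplicate (subject, visit) rows")
    if (long_df.groupby("subject_id")["visit"].nunique() > n_visits).any():
        raise ValueError(f"more than {n_visits} visits for some subject")
    complete = long_df.dropna(subset=["sbp", *COVARIATE_COLUMNS])
    picked = (complete.sort_values(["subject_id", "visit"])
              .groupby("subject_id", as_index=False).first())
    n_in = long_df["subject_id"].nunique()
    n_dropped = n_in - len(picked)
    if n_dropped:
        logger.info("first-visit selection: %d of %d subjects dropped "
                    "(no complete visit)", n_dropped, n_in)
    return picked.rename(columns={"visit": "source_visit"}).reset_index(drop=True)


def build_covariate_matrix(records: pd.DataFrame):
    """n x 4 fixed-covariate matrix in the order (age, sex, smoke, bpmed).

    The intercept is handled separately by the regression model.  A
    constant column triggers a rank-deficiency warning.
    """
    Z = records.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=np.float64)
    if np.isnan(Z).any():
        raise ValueError("covariates contain missing values")
    for j, name in enumerate(COVARIATE_COLUMNS):
        if len(Z) and np.all(Z[:, j] == Z[0, j]):
            warnings.warn(f"covariate column '{name}' is constant; the model "
                          "with an intercept is rank deficient", UserWarning)
    return Z, list(COVARIATE_COLUMNS)


def prepare_cohort(long_df: pd.DataFrame):
    """Longitudinal table -> analysis-ready cohort.

    Returns ``(cohort, transform)`` where ``cohort`` has one row per
    subject with the standardized response ``y``, the source visit and
    the covariates, and ``transform`` records the logSBP mean/sd.
    """
    picked = select_first_visit(long_df)
    if len(picked) < 2:
        raise ValueError("fewer than 2 subjects with a complete visit")
    y, transform = log_standardize(picked["sbp"].to_numpy())
    cohort = picked.copy()
    cohort.insert(1, "y", y)
    return cohort, transform
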