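"""Age-acceleration residuals: standardization, quantile categories, outlier rule.

Acceleration is the residual from an ordinary least-squares regression of a
biological-age measure on chronological age over the analysis set; positive
values mean "older than expected".  Each acceleration measure is standardized
separately (mean 0, SD 1).  Subjects whose biological age falls outside
mean +/- 5 SD (single pass, strict inequality) are excluded before analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def residual_acceleration(ba, ca) -> np.ndarray:
    """OLS residuals of biological age on chronological age."""
    ba = np.asarray(ba, float)
    ca = np.asarray(ca, float)
    if ba.shape != ca.shape:
        raise ValueError("length mismatch between BA and CA")
    if ba.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(ca) == 0:
        raise ValueError("chronological age is constant; residualization undefined")
    cam = ca.mean()
    beta = np.sum((ca - cam) * (ba - ba.mean())) / np.sum((ca - cam) ** 2)
    alpha = ba.mean() - beta * cam
    return ba - (alpha + beta * ca)


def standardize(raw) -> np.ndarray:
    """z = (raw - mean) / SD; raises on zero spread."""
    raw = np.asarray(raw, float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero standard deviation; cannot standardize")
    return (raw - raw.mean()) / sd


def exclude_ba_outliers(ba, n_sd: float = 5.0) -> np.ndarray:
    """Keep-mask for biological ages within mean +/- n_sd SD.

    Single pass: mean and SD come from the pre-exclusion set.  The boundary
    value exactly at n_sd SD is retained (strict inequality).
    """
    ba = np.asarray(ba, float)
    if ba.size < 2:
        raise ValueError("need at least 2 subjects")
    mu, sd = ba.mean(), ba.std()
    if sd == 0:
        return np.ones(ba.size, dtype=bool)
    return np.abs(ba - mu) <= n_sd * sd


def quantile_categories(values, k: int, labels: list[str] | None = None) -> np.ndarray:
    """Sample-quantile categories Q1 (lowest) .. Qk.

    Cutpoints sit at the i/k sample quantiles (linear interpolation); a value
    exactly on a cutpoint goes to the lower category.
    """
    values = np.asarray(values, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(values).size < k:
        raise ValueError("too few distinct values for the requested categories")
    cuts = np.quantile(values, np.arange(1, k) / k)
    idx = np.zeros(values.size, dtype=int)
    for c in cuts:
        idx += values > c
    if labels is None:
        labels = [f"Q{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must equal k")
    return np.asarray(labels, dtype=object)[idx]


class AgeAcceleration(TransformerMixin, BaseEstimator):
    """Residual age-acceleration transformer for one or more BA measures.

    fit() estimates the BA-on-CA regression line and the standardization
    moments on the analysis set; transform() returns raw residuals, z scores
    and quartile labels.  Fitting and transforming the same set reproduces the
    single-sample workflow.

    Parameters
    ----------
    ba_cols : biological-age columns to residualize (each independently).
    age_col : chronological-age column.
    k : number of quantile categories for labelling (4 = quartiles).
    """

    def __init__(self, ba_cols=("bioage", "phenoage"), age_col="age", k=4):
        self.ba_cols = ba_cols
        self.age_col = age_col
        self.k = k

    def fit(self, X: pd.DataFrame, y=None) -> "AgeAcceleration":
        ca = X[self.age_col].to_numpy(float)
        self.lines_ = {}
        self.moments_ = {}
        self.cuts_ = {}
        for col in self.ba_cols:
            ba = X[col].to_numpy(float)
            resid = residual_acceleration(ba, ca)
            cam = ca.mean()
            beta = np.sum((ca - cam) * (ba - ba.mean())) / np.sum((ca - cam) ** 2)
            alpha = ba.mean() - beta * cam
            self.lines_[col] = (float(alpha), float(beta))
            sd = resid.std()
            if sd == 0:
                raise ValueError(f"degenerate (noise-free) acceleration for {col!r}")
            self.moments_[col] = (float(resid.mean()), float(sd))
            z = (resid - resid.mean()) / sd
            self.cuts_[col] = np.quantile(z, np.arange(1, self.k) / self.k)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=X.index)
        ca = X[self.age_col].to_numpy(float)
        for col in self.ba_cols:
            alpha, beta = self.lines_[col]
            raw = X[col].to_numpy(float) - (alpha + beta * ca)
            mu, sd = self.moments_[col]
            z = (raw - mu) / sd
            idx = np.zeros(z.size, dtype=int)
            for c in self.cuts_[col]:
                idx += z > c
            out[f"{col}_accel"] = raw
            out[f"{col}_accel_z"] = z
            out[f"{col}_accel_q"] = np.asarray([f"Q{i + 1}" for i in range(self.k)], dtype=object)[idx]
        return out


@dataclass
class AccelTable:
    """Convenience bundle: augmented table plus the exclusion bookkeeping."""

    table: pd.DataFrame
    kept_mask: np.ndarray
    n_excluded: int


def build_accel_table(df: pd.DataFrame, ba_cols=("bioage", "phenoage"), age_col="age",
                      n_sd: float = 5.0, outlier_on: tuple | None = None) -> AccelTable:
    """Apply the outlier rule then residualize/standardize/categorize.

    ``outlier_on`` restricts the +/- n_sd exclusion to a subset of the BA
    measures; by default the rule is applied to each measure and the exclusion
    masks are unioned.
    """
    outlier_on = tuple(outlier_on) if outlier_on is not None else tuple(ba_cols)
    keep = np.ones(len(df), dtype=bool)
    for col in outlier_on:
        keep &= exclude_ba_outliers(df[col].to_numpy(float), n_sd=n_sd)
    kept = df.loc[keep].copy()
    acc = AgeAcceleration(ba_cols=ba_cols, age_col=age_col).fit(kept).transform(kept)
    return AccelTable(table=pd.concat([kept, acc], axis=1), kept_mask=keep,
                      n_excluded=int((~keep).sum()))
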