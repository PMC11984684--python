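"""Klemera-Doubal biological age (BioAge), sex-stratified.

The estimator combines per-biomarker linear regressions on chronological age
(CA) in a reference (training) sample into a weighted biological-age estimate:

    BioAge = [ sum_i (x_i - q_i) k_i / s_i^2  +  CA / s_BA^2 ]
             / [ sum_i (k_i / s_i)^2  +  1 / s_BA^2 ]

where, for biomarker i regressed on age within a sex stratum, q_i is the
intercept, k_i the slope (biomarker units per year) and s_i the residual root
mean squared error.  s_BA anchors the chronological-age term; here it is the
square root of the variance in CA explained by the full biomarker set in the
stratum (from a multiple regression of CA on the biomarkers), and it can be
overridden to test other conventions.

Training and application are strictly separated: parameters are estimated once
on the reference sample and then projected, unchanged, onto any number of
downstream samples.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

logger = logging.getLogger(__name__)

_S_FLOOR_FRAC = 1e-6  # floor on s_i, as a fraction of the biomarker SD


@dataclass
class KDMStratum:
    """Fitted Klemera-Doubal constants for one sex stratum."""

    biomarkers: list[str]
    q: np.ndarray       # per-biomarker intercept (biomarker units)
    k: np.ndarray       # per-biomarker slope (biomarker units / year)
    s: np.ndarray       # per-biomarker residual RMSE (biomarker units)
    s_ba: float         # CA-anchor scale (years)
    n: int

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if len(self.biomarkers) == 0:
            raise ValueError("empty biomarker list")
        if len(set(self.biomarkers)) != len(self.biomarkers):
            raise ValueError("duplicate biomarkers")
        if not np.all(self.s > 0):
            raise ValueError("all s_i must be > 0")
        if not self.s_ba > 0:
            raise ValueError("s_BA must be > 0")
        if np.any(self.k == 0):
            raise ValueError("zero slope makes the KDM term undefined")


@dataclass
class KDMParams:
    """Per-sex Klemera-Doubal parameters plus bookkeeping for serialization."""

    strata: dict[str, KDMStratum] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            sex: {**asdict(st), "q": st.q.tolist(), "k": st.k.tolist(), "s": st.s.tolist()}
            for sex, st in self.strata.items()
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KDMParams":
        payload = json.loads(text)
        return cls(strata={sex: KDMStratum(**d) for sex, d in payload.items()})


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple least squares of y on x: (intercept, slope, rmse)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("constant regressor")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(intercept), float(slope), rmse


def fit_kdm_stratum(
    df: pd.DataFrame,
    biomarkers: list[str],
    age_col: str = "age",
    min_rows: int = 50,
    s_ba: float | None = None,
    drop_flat_slopes: bool = False,
    flat_t: float = 2.0,
) -> KDMStratum:
    """Estimate (q, k, s) per biomarker and s_BA within one sex stratum."""
    sub = df[[age_col, *biomarkers]].dropna()
    n = len(sub)
    if n < min_rows:
        raise ValueError(f"need >= {min_rows} complete rows, got {n}")
    age = sub[age_col].to_numpy(float)
    if age.std() == 0:
        raise ValueError("constant chronological age in stratum")

    kept, qs, ks, ss = [], [], [], []
    for bm in biomarkers:
        y = sub[bm].to_numpy(float)
        sd = y.std()
        if sd == 0:
            raise ValueError(f"biomarker {bm!r} has zero variance")
        q, k, s = _ols_line(age, y)
        # slope t-statistic against zero
        se_k = (s * np.sqrt(n / max(n - 2, 1))) / (age.std() * np.sqrt(n))
        if k == 0 or (drop_flat_slopes and se_k > 0 and abs(k / se_k) < flat_t):
            logger.warning("dropping biomarker %r: slope %.3g indistinguishable from zero", bm, k)
            continue
        s = max(s, _S_FLOOR_FRAC * sd)  # guard: noise-free fixtures give s = 0
        kept.append(bm)
        qs.append(q)
        ks.append(k)
        ss.append(s)
    if not kept:
        raise ValueError("no biomarkers retained")

    if s_ba is None:
        # sqrt of the CA variance explained by the biomarker set (multiple OLS)
        Xb = np.column_stack([np.ones(n), sub[kept].to_numpy(float)])
        coef, *_ = np.linalg.lstsq(Xb, age, rcond=None)
        fitted = Xb @ coef
        explained = float(np.var(fitted))
        s_ba = float(np.sqrt(max(explained, (_S_FLOOR_FRAC * age.std()) ** 2)))
    return KDMStratum(biomarkers=kept, q=np.array(qs), k=np.array(ks), s=np.array(ss), s_ba=float(s_ba), n=n)


def kdm_bioage_values(panel: np.ndarray, ca: np.ndarray, stratum: KDMStratum) -> np.ndarray:
    """Apply the Klemera-Doubal formula to a (n, m) biomarker panel."""
    panel = np.atleast_2d(np.asarray(panel, float))
    ca = np.atleast_1d(np.asarray(ca, float))
    if panel.shape[1] != len(stratum.biomarkers):
        raise ValueError("panel width does not match the fitted biomarker list")
    if not np.all(np.isfinite(panel)) or not np.all(np.isfinite(ca)):
        raise ValueError("non-finite biomarker or age values")
    w = stratum.k / stratum.s**2
    num = (panel - stratum.q) @ w + ca / stratum.s_ba**2
    den = np.sum((stratum.k / stratum.s) ** 2) + 1.0 / stratum.s_ba**2
    return num / den


class KDMBioAge(BaseEstimator):
    """Sex-stratified Klemera-Doubal biological-age estimator.

    Parameters
    ----------
    biomarkers : ordered biomarker column names (the 9-marker clinical panel by
        default: FEV1, SBP, total cholesterol, HbA1c, albumin, creatinine,
        ln-free CRP, alkaline phosphatase, blood urea nitrogen).
    age_col, sex_col : column names for chronological age (years) and sex.
    s_ba : optional override for the CA-anchor scale (years); estimated from
        the training stratum when None.
    drop_flat_slopes : drop biomarkers whose age slope has |t| < 2 (off by
        default: the published algorithm uses a fixed list).

    Attributes
    ----------
    params_ : KDMParams with one fitted stratum per sex.
    """

    DEFAULT_PANEL = [
        "fev1", "sbp", "total_cholesterol", "hba1c", "albumin",
        "creatinine", "crp", "alkaline_phosphatase", "blood_urea_nitrogen",
    ]

    def __init__(self, biomarkers=None, age_col="age", sex_col="sex",
                 s_ba=None, drop_flat_slopes=False, min_rows=50):
        self.biomarkers = biomarkers
        self.age_col = age_col
        self.sex_col = sex_col
        self.s_ba = s_ba
        self.drop_flat_slopes = drop_flat_slopes
        self.min_rows = min_rows

    def _panel(self):
        return list(self.biomarkers) if self.biomarkers is not None else list(self.DEFAULT_PANEL)

    def fit(self, X: pd.DataFrame, y=None) -> "KDMBioAge":
        """Estimate per-sex (q, k, s, s_BA) on a reference sample."""
        panel = self._panel()
        missing = [c for c in (self.age_col, self.sex_col, *panel) if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sexes = sorted(X[self.sex_col].dropna().unique().tolist())
        if not sexes:
            raise ValueError("no sex strata present")
        strata = {}
        for sex in sexes:
            sub = X[X[self.sex_col] == sex]
            strata[str(sex)] = fit_kdm_stratum(
                sub, panel, age_col=self.age_col, min_rows=self.min_rows,
                s_ba=self.s_ba, drop_flat_slopes=self.drop_flat_slopes,
            )
        self.params_ = KDMParams(strata=strata)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Project fitted parameters onto a new sample; returns BioAge in years."""
        if not hasattr(self, "params_"):
            raise NotFittedError("call fit() on a reference sample first")
        out = np.full(len(X), np.nan)
        for sex, st in self.params_.strata.items():
            mask = (X[self.sex_col].astype(str) == sex).to_numpy()
            if not mask.any():
                continue
            panel = X.loc[mask, st.biomarkers]
            if panel.isna().any().any():
                raise ValueError("missing biomarker values; impute or exclude first")
            out[mask] = kdm_bioage_values(
                panel.to_numpy(float), X.loc[mask, self.age_col].to_numpy(float), st
            )
        unseen = np.isnan(out) & X[self.sex_col].notna().to_numpy()
        if unseen.any():
            levels = sorted(X.loc[unseen, self.sex_col].astype(str).unique())
            raise ValueError(f"sex strata not seen in training: {levels}")
        return out


def fit_kdm(reference: pd.DataFrame, biomarkers: list[str], sex: str | None = None,
            **kwargs) -> KDMStratum | KDMParams:
    """Thin functional wrapper over :class:`KDMBioAge` / :func:`fit_kdm_stratum`.

    With ``sex`` given, fits a single stratum on that subset; otherwise fits
    all strata and returns :class:`KDMParams`.
    """
    if sex is not None:
        sub = reference[reference["sex"] == sex]
        return fit_kdm_stratum(sub, biomarkers, **kwargs)
    est = KDMBioAge(biomarkers=biomarkers, **kwargs)
    return est.fit(reference).params_


def kdm_bioage(panel, ca, stratum: KDMStratum):
    """Functional form of the KDM formula for one or more subjects."""
    res = kdm_bioage_values(panel, ca, stratum)
    return float(res[0]) if np.ndim(ca) == 0 else res
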