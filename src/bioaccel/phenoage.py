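"""Phenotypic age (PhenoAge) from nine clinical biomarkers plus chronological age.

PhenoAge maps a Gompertz 10-year mortality risk, driven by a fixed published
linear predictor, back onto an age scale:

    xb   = b0 + sum_i w_i x_i + w_age * CA          (CRP on the natural-log scale)
    risk = 1 - exp(-exp(xb) * (exp(120 * gamma) - 1) / gamma)
    PhenoAge = 141.50225 + ln(-0.0055305 * ln(1 - risk)) / 0.090165

The coefficients are published constants and ship as a versioned, checksummed
data file; they are only meaningful in their native units (albumin g/L,
creatinine umol/L, glucose mmol/L, CRP mg/dL inside the log, alkaline
phosphatase U/L, WBC 10^3 cells/uL).  A :class:`UnitSpec` converts other lab
conventions (e.g. albumin g/dL, creatinine mg/dL) into those units.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

RISK_CLAMP_EPS = 1e-15  # mortality risk clamped to (eps, 1 - eps)

PHENOAGE_BIOMARKERS = [
    "albumin", "creatinine", "glucose", "crp", "lymphocyte_pct",
    "mcv", "rdw", "alkaline_phosphatase", "wbc",
]


@dataclass(frozen=True)
class PhenoAgeCoeffs:
    """Published PhenoAge constants (immutable)."""

    intercept: float
    weights: dict  # keys: albumin, creatinine, glucose, log_crp, lymphocyte_pct, mcv, rdw, alkaline_phosphatase, wbc, age
    gamma: float
    horizon_months: float
    outer_offset: float
    outer_scale: float
    outer_denominator: float

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _canonical_payload(raw: dict) -> str:
    keep = {k: raw[k] for k in ("intercept", "weights", "gamma", "horizon_months", "outer")}
    return json.dumps(keep, sort_keys=True, separators=(",", ":"))


def load_coeffs(original_denominator: bool = False) -> PhenoAgeCoeffs:
    """Load the bundled coefficient file, verifying its checksum.

    ``original_denominator=True`` switches the outer denominator from the
    default 0.090165 to 0.09165, the constant used in the original PhenoAge
    publication; the two values circulate in the literature and the package
    exposes both rather than silently preferring one.
    """
    raw = json.loads(resources.files("bioaccel.data").joinpath("phenoage_coefficients.json").read_text())
    digest = hashlib.sha256(_canonical_payload(raw).encode()).hexdigest()
    if digest != raw["sha256"]:
        raise ValueError("phenoage coefficient file failed its checksum")
    den = raw["outer"]["denominator_alt"] if original_denominator else raw["outer"]["denominator"]
    return PhenoAgeCoeffs(
        intercept=raw["intercept"],
        weights=dict(raw["weights"]),
        gamma=raw["gamma"],
        horizon_months=raw["horizon_months"],
        outer_offset=raw["outer"]["offset"],
        outer_scale=raw["outer"]["scale"],
        outer_denominator=den,
    )


@dataclass
class UnitSpec:
    """Per-biomarker multiplicative conversion into coefficient-native units.

    ``factors`` maps biomarker name -> factor such that
    native_value = factor * input_value.  ``crp_floor`` optionally declares a
    detection floor (in native mg/dL); CRP values at or below the floor are
    replaced by floor / sqrt(2) before the log.
    """

    factors: dict = field(default_factory=dict)
    crp_floor: float | None = None

    def convert(self, name: str, value):
        return np.asarray(value, float) * float(self.factors.get(name, 1.0))

    @classmethod
    def identity(cls) -> "UnitSpec":
        return cls()

    @classmethod
    def us_conventional(cls) -> "UnitSpec":
        """Albumin g/dL, creatinine mg/dL, glucose mg/dL, CRP mg/L inputs."""
        return cls(factors={"albumin": 10.0, "creatinine": 88.42, "glucose": 1 / 18.016, "crp": 0.1})


def linear_predictor(panel, ca, coeffs: PhenoAgeCoeffs | None = None,
                     units: UnitSpec | None = None) -> np.ndarray:
    """The Gompertz linear predictor xb (dimensionless)."""
    coeffs = coeffs or load_coeffs()
    units = units or UnitSpec.identity()
    if isinstance(panel, pd.DataFrame):
        panel = {k: panel[k].to_numpy(float) for k in PHENOAGE_BIOMARKERS}
    missing = [k for k in PHENOAGE_BIOMARKERS if k not in panel]
    if missing:
        raise ValueError(f"missing biomarkers: {missing}")
    ca = np.asarray(ca, float)
    vals = {k: units.convert(k, panel[k]) for k in PHENOAGE_BIOMARKERS}
    crp = vals["crp"]
    if units.crp_floor is not None:
        crp = np.where(crp <= units.crp_floor, units.crp_floor / np.sqrt(2.0), crp)
    if np.any(crp <= 0):
        raise ValueError("CRP must be positive (declare a detection floor in UnitSpec to handle zeros)")
    w = coeffs.weights
    xb = (
        coeffs.intercept
        + w["albumin"] * vals["albumin"]
        + w["creatinine"] * vals["creatinine"]
        + w["glucose"] * vals["glucose"]
        + w["log_crp"] * np.log(crp)
        + w["lymphocyte_pct"] * vals["lymphocyte_pct"]
        + w["mcv"] * vals["mcv"]
        + w["rdw"] * vals["rdw"]
        + w["alkaline_phosphatase"] * vals["alkaline_phosphatase"]
        + w["wbc"] * vals["wbc"]
        + w["age"] * ca
    )
    return xb


def mortality_risk(xb, coeffs: PhenoAgeCoeffs | None = None) -> np.ndarray:
    """Gompertz mortality risk over the 120-month horizon, in (0, 1)."""
    coeffs = coeffs or load_coeffs()
    xb = np.asarray(xb, float)
    if not np.all(np.isfinite(xb)):
        raise ValueError("non-finite linear predictor")
    scale = (np.exp(coeffs.horizon_months * coeffs.gamma) - 1.0) / coeffs.gamma
    # log1p/expm1 keep precision in the tails; clamp guards the outer log
    risk = -np.expm1(-np.exp(xb) * scale)
    clamped = (risk <= RISK_CLAMP_EPS) | (risk >= 1 - RISK_CLAMP_EPS)
    if np.any(clamped):
        warnings.warn("mortality risk at clamp boundary; PhenoAge is saturated there", RuntimeWarning)
    return np.clip(risk, RISK_CLAMP_EPS, 1 - RISK_CLAMP_EPS)


def phenoage_from_risk(risk, coeffs: PhenoAgeCoeffs | None = None) -> np.ndarray:
    coeffs = coeffs or load_coeffs()
    risk = np.asarray(risk, float)
    inner = coeffs.outer_scale * np.log1p(-risk)   # -0.0055305 * ln(1 - risk) > 0
    return coeffs.outer_offset + np.log(inner) / coeffs.outer_denominator


def phenoage(panel, ca, coeffs: PhenoAgeCoeffs | None = None,
             units: UnitSpec | None = None) -> np.ndarray:
    """PhenoAge in years: composition of the three published maps."""
    coeffs = coeffs or load_coeffs()
    xb = linear_predictor(panel, ca, coeffs, units)
    return phenoage_from_risk(mortality_risk(xb, coeffs), coeffs)


class PhenoAgeClock(BaseEstimator):
    """PhenoAge as a (stateless) sklearn-style estimator.

    The coefficients are published constants, so ``fit`` only records the
    configuration; ``predict`` maps a biomarker panel to PhenoAge in years.

    Parameters
    ----------
    age_col : chronological-age column, years.
    units : UnitSpec for input-unit conversion (identity by default).
    original_denominator : use 0.09165 instead of 0.090165 in the outer map.
    """

    def __init__(self, age_col="age", units=None, original_denominator=False):
        self.age_col = age_col
        self.units = units
        self.original_denominator = original_denominator

    def fit(self, X=None, y=None) -> "PhenoAgeClock":
        self.coeffs_ = load_coeffs(original_denominator=self.original_denominator)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "coeffs_"):
            self.fit()
        return phenoage(X, X[self.age_col].to_numpy(float), self.coeffs_, self.units)
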