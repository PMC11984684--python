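"""Synthetic reference and analysis cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale, with every parameter explicit so recovery tests can
compare estimates against truth:

* a reference (training) sample aged 40-69 with sex-specific linear
  biomarker-age trends plus Gaussian noise and a latent frailty shared
  between biomarker deviations and mortality, so biomarker-based clocks
  predict death;
* an analysis cohort in which each subject's biological-age acceleration is
  *induced in the biomarkers* by shifting them along the fitted
  Klemera-Doubal loadings — acceleration must be recovered from the panel,
  never read from a hidden column;
* exponential event times (constant baseline hazard) whose log hazard is
  linear in standardized acceleration, GRS and the behavior score, or — in
  joint-grid mode — follows a configurable 3x4 rate-ratio grid over
  (GRS tertile x acceleration quartile);
* behavior components, 12 SNP dosages and a socioeconomic covariate block
  drawn independently of exposure by default, with a confounding knob.

Default parameter values are calibrated once to the cohort the pipeline is
designed for: age 40-69, 53.9% female, baseline heart-failure hazard
2.5e-3 per person-year with a 13.5-year censoring horizon, hazard ratio 1.45
per SD of acceleration, 1.62 per GRS point, and a behavior effect of
HR 0.76 per 10 points of which roughly 21% flows through acceleration.
All randomness comes from one seeded generator; identical config + seed
gives byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .behavior import behavior_score_table, ScoringRules
from .grs import GRSWeights, weighted_grs
from .kdm import KDMParams, kdm_bioage_values
from .acceleration import quantile_categories

BIOMARKERS = [
    "fev1", "sbp", "total_cholesterol", "hba1c", "albumin", "creatinine",
    "crp", "alkaline_phosphatase", "blood_urea_nitrogen", "glucose",
    "lymphocyte_pct", "mcv", "rdw", "wbc",
]

# (mean at age 56.5, slope per year, residual SD, direction of "worse")
_BIOMARKER_BASE = {
    "fev1":                 (2.89, -0.025, 0.60, -1),
    "sbp":                  (137.7, 0.45, 17.0, +1),
    "total_cholesterol":    (221.5, 0.30, 43.0, +1),
    "hba1c":                (5.42, 0.012, 0.55, +1),
    "albumin":              (45.3, -0.05, 2.5, -1),   # g/L
    "creatinine":           (72.5, 0.15, 14.0, +1),   # umol/L
    "crp":                  (0.24, 0.004, 0.30, +1),  # mg/dL
    "alkaline_phosphatase": (82.7, 0.20, 25.0, +1),
    "blood_urea_nitrogen":  (15.15, 0.08, 3.6, +1),
    "glucose":              (5.10, 0.015, 1.00, +1),  # mmol/L
    "lymphocyte_pct":       (28.8, -0.08, 7.2, -1),
    "mcv":                  (82.8, 0.04, 5.2, +1),
    "rdw":                  (13.45, 0.012, 0.90, +1),
    "wbc":                  (6.84, 0.010, 1.80, +1),
}

# additive male - female mean differences, in biomarker units
_MALE_OFFSET = {
    "fev1": 0.80, "sbp": 4.0, "creatinine": 14.0, "albumin": 0.8,
    "total_cholesterol": -8.0, "lymphocyte_pct": -1.5, "blood_urea_nitrogen": 1.0,
}

_REF_AGE = 56.5

# default 3x4 rate-ratio grid (GRS tertile x acceleration quartile);
# cell (1,1) is the reference and the top corner mirrors the headline joint HR
DEFAULT_JOINT_GRID = [
    [1.00, 1.25, 1.60, 2.20],
    [1.10, 1.40, 1.80, 2.45],
    [1.23, 1.55, 2.00, 2.69],
]


def _default_biomarker_models() -> dict:
    models = {}
    for bm, (mean, slope, sd, _sign) in _BIOMARKER_BASE.items():
        female = {"intercept": mean - slope * _REF_AGE, "slope": slope, "sd": sd}
        male = dict(female)
        male["intercept"] = female["intercept"] + _MALE_OFFSET.get(bm, 0.0)
        models[bm] = {"female": female, "male": male}
    return models


def _default_maf():
    return [0.12, 0.18, 0.22, 0.27, 0.31, 0.35, 0.38, 0.41, 0.44, 0.47, 0.49, 0.50]


def _default_grs_beta():
    return GRSWeights.synthetic_default().beta.tolist()


@dataclass
class SynthConfig:
    """Ground-truth parameters for the synthetic cohorts."""

    n_reference: int = 10_000
    n_cohort: int = 20_000
    seed: int = 0
    age_range: tuple = (40.0, 69.0)
    female_fraction: float = 0.539
    biomarker_models: dict = field(default_factory=_default_biomarker_models)
    # hazard structure
    true_loghr_per_sd_accel: float = math.log(1.45)
    grs_loghr_per_point: float = math.log(1.62)
    behavior_effect_on_accel: float = -0.156   # SD of acceleration per 10 points
    behavior_direct_loghr_per_10pt: float = -0.216
    grs_maf: list = field(default_factory=_default_maf)
    grs_beta: list = field(default_factory=_default_grs_beta)
    joint_rate_ratio_grid: list = field(default_factory=lambda: [row[:] for row in DEFAULT_JOINT_GRID])
    baseline_hazard: float = 8915 / 3_564_477   # events per person-year
    censor_horizon: float = 13.5                # years
    # latent structure
    accel_sd_years: float = 4.39
    frailty_strength: float = 0.30
    confounding_strength: float = 0.0
    # reference-sample mortality
    mortality_baseline_hazard: float = 0.010
    mortality_horizon: float = 20.0
    mortality_frailty_loghr: float = 0.80
    mortality_age_loghr: float = 0.07

    def __post_init__(self):
        if self.n_reference <= 0 or self.n_cohort <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("degenerate age range")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        grid = np.asarray(self.joint_rate_ratio_grid, float)
        if grid.shape != (3, 4):
            raise ValueError("joint_rate_ratio_grid must be 3x4")
        if not np.isclose(grid[0, 0], 1.0):
            raise ValueError("grid reference cell (1,1) must equal 1")
        if len(self.grs_maf) != 12 or len(self.grs_beta) != 12:
            raise ValueError("grs_maf and grs_beta must have length 12")
        for bm, per_sex in self.biomarker_models.items():
            for sex, m in per_sex.items():
                if m["sd"] < 0:
                    raise ValueError(f"negative residual SD for {bm}/{sex}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SynthConfig":
        d = yaml.safe_load(text)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def truth_dict(self) -> dict:
        """Ground-truth sidecar for recovery tests."""
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))


def _draw_base(config: SynthConfig, n: int, rng: np.random.Generator):
    """Ages, sexes, frailty and biomarkers with linear age trends."""
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.uniform(size=n) < config.female_fraction, "female", "male")
    frailty = rng.normal(size=n)
    df = pd.DataFrame({"age": age, "sex": sex, "frailty": frailty})
    for bm in BIOMARKERS:
        models = config.biomarker_models[bm]
        sign = _BIOMARKER_BASE[bm][3]
        vals = np.empty(n)
        noise = rng.normal(size=n)
        for s in ("female", "male"):
            m = models[s]
            mask = sex == s
            vals[mask] = m["intercept"] + m["slope"] * age[mask] + m["sd"] * noise[mask]
        vals += sign * config.frailty_strength * models["female"]["sd"] * frailty
        if bm == "crp":
            vals = np.clip(vals, 0.01, None)  # CRP is positive; log taken downstream
        df[bm] = vals
    return df


def generate_reference(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Training sample with mortality follow-up (a stand-in reference cohort)."""
    rng = rng or np.random.default_rng(config.seed)
    df = _draw_base(config, config.n_reference, rng)
    rate = config.mortality_baseline_hazard * np.exp(
        config.mortality_frailty_loghr * df["frailty"].to_numpy()
        + config.mortality_age_loghr * (df["age"].to_numpy() - _REF_AGE)
    )
    t_death = rng.exponential(1.0 / rate)
    df["time"] = np.minimum(t_death, config.mortality_horizon)
    df["event"] = (t_death <= config.mortality_horizon).astype(int)
    df.insert(0, "subject_id", np.arange(config.n_reference))
    return df.drop(columns="frailty")


_EDU = (["<=10y", "11-15y", ">15y", "unknown"], [0.323, 0.180, 0.491, 0.006])
_INCOME = (["<18k", "18-31k", "31-52k", ">52k", "unknown"], [0.180, 0.221, 0.236, 0.241, 0.122])
_EMPLOY = (["employed", "unemployed", "unknown"], [0.617, 0.380, 0.003])
_CENTER = (["england", "scotland", "wales"], [0.913, 0.042, 0.045])
_ALCOHOL = (["never", "occasional", "1-2_per_week", "3-4_per_week", "daily"],
            [0.062, 0.213, 0.263, 0.245, 0.217])
_TOBACCO = (["never", "former_quit_5y_plus", "former_quit_1_5y", "former_quit_lt_1y", "current"],
            [0.55, 0.25, 0.05, 0.02, 0.13])


def _draw_cat(rng, n, table):
    levels, probs = table
    return np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=probs)]


def generate_cohort(
    config: SynthConfig,
    kdm: KDMParams,
    mode: str = "per_sd",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Analysis cohort with induced acceleration and survival outcomes.

    ``mode='per_sd'``: log hazard linear in standardized acceleration, GRS
    and behavior.  ``mode='joint_grid'``: hazard follows the configured 3x4
    rate-ratio grid over (GRS tertile, acceleration quartile); other effects
    are off so crude cell rate ratios converge to the grid.
    """
    if kdm is None or not getattr(kdm, "strata", None):
        raise ValueError("fitted KDM parameters are required")
    if mode not in ("per_sd", "joint_grid"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_cohort
    df = _draw_base(config, n, rng)

    # behavior components
    df["diet_count"] = rng.binomial(10, 0.35, size=n)
    df["mvpa_minutes"] = np.clip(rng.normal(145, 95, size=n), 0, None)
    df["tobacco_category"] = _draw_cat(rng, n, _TOBACCO)
    df["secondhand_smoke"] = (rng.uniform(size=n) < 0.08).astype(int)
    df["sleep_hours"] = np.clip(rng.normal(7.15, 1.0, size=n), 2.0, 12.0)
    df["bmi"] = np.clip(rng.normal(27.4, 4.6, size=n), 15.0, 60.0)
    scores = behavior_score_table(df, ScoringRules.default())
    df = pd.concat([df, scores], axis=1)
    behavior = df["behavior_score"].to_numpy()

    # covariate block (independent of exposure unless confounding is dialed in)
    df["center"] = _draw_cat(rng, n, _CENTER)
    df["education"] = _draw_cat(rng, n, _EDU)
    df["income"] = _draw_cat(rng, n, _INCOME)
    df["employment"] = _draw_cat(rng, n, _EMPLOY)
    df["alcohol"] = _draw_cat(rng, n, _ALCOHOL)
    depr = np.clip(rng.normal(20.0, 12.0, size=n), 1.0, 80.0)
    df["deprivation"] = depr
    for i in range(1, 11):
        df[f"pc{i}"] = rng.normal(size=n)
    df["batch"] = _draw_cat(rng, n, (["batch_1", "batch_2"], [0.5, 0.5]))

    # genotypes and GRS
    maf = np.asarray(config.grs_maf, float)
    dosages = rng.binomial(2, maf, size=(n, 12)).astype(float)
    weights = GRSWeights(
        snps=[f"snp_{i + 1:02d}" for i in range(12)],
        effect_alleles=["A"] * 12,
        beta=np.asarray(config.grs_beta, float),
    )
    for i in range(12):
        df[f"snp_{i + 1:02d}"] = dosages[:, i]
    grs = np.asarray(weighted_grs(dosages, weights), float)
    df["grs"] = grs

    # latent standardized acceleration: behavior pathway + optional
    # confounding + independent noise, total variance ~ 1
    depr_z = (depr - depr.mean()) / depr.std()
    systematic = (
        config.behavior_effect_on_accel * (behavior - behavior.mean()) / 10.0
        + config.confounding_strength * depr_z
    )
    eps_sd = math.sqrt(max(1.0 - float(np.var(systematic)), 0.05))
    accel_z = systematic + eps_sd * rng.normal(size=n)

    # realize the acceleration in the biomarkers: shift the panel along the
    # fitted KDM loadings so the measured BioAge residual equals the latent
    accel_years = accel_z * config.accel_sd_years
    age = df["age"].to_numpy()
    sexes = df["sex"].to_numpy()
    ba0 = np.empty(n)
    for sex, st in kdm.strata.items():
        mask = sexes == sex
        ba0[mask] = kdm_bioage_values(df.loc[mask, st.biomarkers].to_numpy(float), age[mask], st)
    beta_line = np.polyfit(age, ba0, 1)
    resid0 = ba0 - np.polyval(beta_line, age)
    delta = accel_years - resid0
    for sex, st in kdm.strata.items():
        mask = sexes == sex
        D = np.sum((st.k / st.s) ** 2) + 1.0 / st.s_ba**2
        c = np.sum(st.k**2 / st.s**2) / D       # BioAge gain per unit shift along k
        shift = np.outer(delta[mask] / c, st.k)
        df.loc[mask, st.biomarkers] = df.loc[mask, st.biomarkers].to_numpy(float) + shift
    df["crp"] = np.clip(df["crp"], 0.01, None)

    # survival outcome
    if mode == "per_sd":
        mean_grs = float(2 * maf @ np.asarray(config.grs_beta, float))
        loglam = (
            np.log(config.baseline_hazard)
            + config.true_loghr_per_sd_accel * accel_z
            + config.grs_loghr_per_point * (grs - mean_grs)
            + config.behavior_direct_loghr_per_10pt * (behavior - behavior.mean()) / 10.0
            + config.confounding_strength * depr_z
        )
    else:
        grid = np.asarray(config.joint_rate_ratio_grid, float)
        tert = quantile_categories(grs, 3, labels=[0, 1, 2]).astype(int)
        quart = quantile_categories(accel_z, 4, labels=[0, 1, 2, 3]).astype(int)
        loglam = np.log(config.baseline_hazard) + np.log(grid[tert, quart])
        df["true_grs_tertile"] = tert
        df["true_accel_quartile"] = quart
    t_event = rng.exponential(np.exp(-loglam))
    df["time"] = np.maximum(np.minimum(t_event, config.censor_horizon), 1e-8)
    df["event"] = (t_event <= config.censor_horizon).astype(int)
    df["true_accel_z"] = accel_z
    df.insert(0, "subject_id", np.arange(n))
    return df.drop(columns="frailty")


def inject_missingness(
    cohort: pd.DataFrame,
    rate: float,
    max_missing_per_subject: int = 1,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Set biomarker cells missing completely at random, capped per row.

    Sampling scheme (documented for the binomial oracle): every biomarker
    cell is independently flagged with probability ``rate``; rows with more
    than ``max_missing_per_subject`` flags are thinned to a uniformly chosen
    subset of that size.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    columns = columns or [c for c in BIOMARKERS if c in cohort.columns]
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    flags = rng.uniform(size=(len(out), len(columns))) < rate
    vals = out[columns].to_numpy(float)
    for i in np.flatnonzero(flags.sum(axis=1) > 0):
        hit = np.flatnonzero(flags[i])
        if hit.size > max_missing_per_subject:
            hit = rng.choice(hit, size=max_missing_per_subject, replace=False)
        vals[i, hit] = np.nan
    out[columns] = vals
    return out


def generate_binary_interaction_cohort(
    n: int,
    hr10: float,
    hr01: float,
    hr11: float,
    p_a: float = 1 / 3,
    p_b: float = 1 / 4,
    baseline_hazard: float = 0.012,
    censor_horizon: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal two-binary-exposure cohort for additive-interaction studies.

    The four exposure cells have rate ratios (1, hr10, hr01, hr11); setting
    hr11 = hr10 + hr01 - 1 yields exact additivity (true RERI = 0).
    """
    rng = np.random.default_rng(seed)
    a = (rng.uniform(size=n) < p_a).astype(int)
    b = (rng.uniform(size=n) < p_b).astype(int)
    rr = np.select(
        [(a == 1) & (b == 1), (a == 1) & (b == 0), (a == 0) & (b == 1)],
        [hr11, hr10, hr01],
        default=1.0,
    )
    t = rng.exponential(1.0 / (baseline_hazard * rr))
    return pd.DataFrame({
        "expo_a": a, "expo_b": b,
        "time": np.minimum(t, censor_horizon),
        "event": (t <= censor_horizon).astype(int),
        "age": rng.uniform(40, 69, size=n),
        "sex": np.asarray(["female", "male"], dtype=object)[(rng.uniform(size=n) < 0.46).astype(int)],
    })


def write_cohort(df: pd.DataFrame, path, truth: dict | None = None) -> None:
    """Tab-delimited table with a header line; optional ground-truth sidecar."""
    df.to_csv(path, sep="\t", index=False)
    if truth is not None:
        sidecar = str(path) + ".truth.json"
        with open(sidecar, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
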