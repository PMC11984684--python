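"""Five-component health-behavior score (diet, activity, tobacco, sleep, BMI).

Each component is scored 0-100 by deterministic band lookup; the overall score
is the arithmetic mean of the five components.  The default band tables ship
as an editable YAML file reconstructed from the AHA Life's Essential 8 scheme;
they are data, not code, so a study can substitute its own protocol.

Diet is special: the 0-10 count of dietary recommendations met is first mapped
to a cohort percentile (fraction of the analysis cohort scoring strictly
lower, plus half the ties, x100) and then banded; with a tiny cohort the
mapping falls back to 10 x count so unit tests stay deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

COMPONENTS = ("diet", "activity", "tobacco", "sleep", "bmi")

TOBACCO_CATEGORIES = (
    "never", "former_quit_5y_plus", "former_quit_1_5y", "former_quit_lt_1y", "current",
)


@dataclass
class ScoringRules:
    """Band tables mapping raw component inputs onto the 0-100 scale.

    Bands are (lo, hi, score) with a closed-left convention: a value at a
    band's lower edge belongs to that band.
    """

    diet_percentile_bands: list = field(default_factory=list)
    diet_min_cohort: int = 50
    activity_bands: list = field(default_factory=list)
    tobacco_scores: dict = field(default_factory=dict)
    secondhand_penalty: float = 20.0
    sleep_bands: list = field(default_factory=list)
    bmi_bands: list = field(default_factory=list)

    @classmethod
    def default(cls) -> "ScoringRules":
        raw = yaml.safe_load(
            resources.files("bioaccel.data").joinpath("behavior_rules.yaml").read_text()
        )
        return cls(**raw)


def _band_lookup(value: float, bands) -> float:
    """Closed-left band lookup; bands are (lo, hi, score)."""
    for lo, hi, score in bands:
        if lo <= value < hi or (value == hi and hi == np.inf):
            return float(score)
    raise ValueError(f"value {value!r} outside every scoring band")


def _band_lookup_vec(values, bands) -> np.ndarray:
    """Vectorized closed-left band lookup."""
    values = np.asarray(values, float)
    out = np.full(values.shape, np.nan)
    for lo, hi, score in bands:
        mask = (values >= lo) & (values < hi)
        out = np.where(mask & np.isnan(out), float(score), out)
    if np.any(np.isnan(out)):
        bad = values[np.isnan(out)][:3]
        raise ValueError(f"values outside every scoring band, e.g. {bad}")
    return out


def diet_recommendations(flags) -> int:
    """Count of the 10 dietary intake recommendations met (each a 0/1 flag)."""
    flags = np.asarray(flags)
    if flags.size != 10:
        raise ValueError("exactly 10 dietary component flags required")
    if np.any(pd.isna(flags)):
        raise ValueError("missing dietary component")
    return int(np.sum(flags != 0))


def diet_percentiles(counts) -> np.ndarray:
    """Percentile rank of each diet count within the cohort (midrank, x100)."""
    counts = np.asarray(counts, float)
    order = np.argsort(counts, kind="stable")
    n = counts.size
    below = np.searchsorted(counts[order], counts, side="left")
    ties = np.searchsorted(counts[order], counts, side="right") - below
    return 100.0 * (below + 0.5 * ties) / n


def component_score(component: str, value, rules: ScoringRules | None = None,
                    cohort_counts=None, secondhand=False) -> float:
    """Score one component on 0-100 from its raw input.

    ``component``: one of diet, activity, tobacco, sleep, bmi.
    Diet takes the 0-10 count; ``cohort_counts`` supplies the analysis-cohort
    counts for the percentile mapping (fallback 10 x count without them).
    Tobacco takes a category from :data:`TOBACCO_CATEGORIES` plus the
    ``secondhand`` exposure flag.
    """
    rules = rules or ScoringRules.default()
    if component == "diet":
        count = float(value)
        if not 0 <= count <= 10:
            raise ValueError("diet count must be in 0..10")
        if cohort_counts is None or len(cohort_counts) < rules.diet_min_cohort:
            return 10.0 * count
        pct = float(diet_percentiles(np.append(np.asarray(cohort_counts, float), count))[-1])
        return _band_lookup(pct, rules.diet_percentile_bands)
    if component == "activity":
        v = float(value)
        if v < 0:
            raise ValueError("negative MVPA minutes")
        return _band_lookup(v, rules.activity_bands)
    if component == "tobacco":
        if value not in rules.tobacco_scores:
            raise ValueError(f"unknown tobacco category {value!r}")
        score = float(rules.tobacco_scores[value])
        if secondhand:
            score = max(score - rules.secondhand_penalty, 0.0)
        return score
    if component == "sleep":
        v = float(value)
        if v < 0:
            raise ValueError("negative sleep hours")
        return _band_lookup(v, rules.sleep_bands)
    if component == "bmi":
        v = float(value)
        if v <= 0:
            raise ValueError("non-positive BMI")
        return _band_lookup(v, rules.bmi_bands)
    raise ValueError(f"unknown component {component!r}")


def overall_score(scores) -> float:
    """Arithmetic mean of the five component scores."""
    scores = np.asarray(scores, float)
    if scores.size != 5:
        raise ValueError("exactly five component scores required")
    if np.any(pd.isna(scores)) or np.any((scores < 0) | (scores > 100)):
        raise ValueError("component scores must be in [0, 100]")
    return float(scores.mean())


def behavior_score_table(df: pd.DataFrame, rules: ScoringRules | None = None) -> pd.DataFrame:
    """Score a cohort table; returns the five component scores plus the mean.

    Expected columns: diet_count (0-10), mvpa_minutes, tobacco_category,
    secondhand_smoke (0/1), sleep_hours, bmi.
    """
    rules = rules or ScoringRules.default()
    counts = df["diet_count"].to_numpy(float)
    if len(df) >= rules.diet_min_cohort:
        diet = _band_lookup_vec(diet_percentiles(counts), rules.diet_percentile_bands)
    else:
        diet = 10.0 * counts
    activity = _band_lookup_vec(df["mvpa_minutes"].to_numpy(float), rules.activity_bands)
    base = df["tobacco_category"].map(rules.tobacco_scores)
    if base.isna().any():
        bad = sorted(df.loc[base.isna(), "tobacco_category"].unique())
        raise ValueError(f"unknown tobacco categories: {bad}")
    tobacco = np.maximum(
        base.to_numpy(float)
        - rules.secondhand_penalty * (df["secondhand_smoke"].to_numpy(float) != 0),
        0.0,
    )
    sleep = _band_lookup_vec(df["sleep_hours"].to_numpy(float), rules.sleep_bands)
    bmi = _band_lookup_vec(df["bmi"].to_numpy(float), rules.bmi_bands)
    out = pd.DataFrame(
        {
            "diet_score": diet,
            "activity_score": activity,
            "tobacco_score": tobacco,
            "sleep_score": sleep,
            "bmi_score": bmi,
        },
        index=df.index,
    )
    out["behavior_score"] = out.mean(axis=1)
    return out
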