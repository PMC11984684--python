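"""Baron-Kenny mediation of a behavior -> survival-outcome association.

The mediator model is linear (OLS of the standardized acceleration on the
exposure plus covariates); the outcome models are Cox proportional-hazards
fits.  Effects are combined on the log-hazard scale by the product method
under a rare-outcome approximation:

    indirect = a * b        (exposure -> mediator -> log hazard)
    direct   = c'           (exposure -> log hazard, mediator in the model)
    proportion mediated = indirect / (indirect + direct)

The alternative convention 1 - c'/c is reported alongside.  Confidence
intervals are percentile bootstrap over subject resamples (all paths refit in
every replicate); the exposure is conventionally scaled per 10 behavior
points by the caller.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hazard import fit_ph, build_design, _resolve_adjustment


@dataclass
class BaronKennyReport:
    """The four Baron-Kenny conditions with the fitted path coefficients."""

    a: float                # exposure -> mediator (linear)
    a_p: float
    c: float                # exposure -> log hazard (total)
    c_p: float
    b_marginal: float       # mediator -> log hazard (without exposure)
    b_marginal_p: float
    b: float                # mediator -> log hazard (with exposure)
    c_prime: float          # exposure -> log hazard (with mediator)
    c_prime_p: float
    conditions: dict = field(default_factory=dict)

    @property
    def all_met(self) -> bool:
        return all(self.conditions.values())


def _ols_path(df: pd.DataFrame, outcome: str, exposure: str, covariates: list[str]):
    """OLS coefficient and p-value of ``exposure`` on ``outcome``."""
    Xe, _ = build_design(df, [exposure])
    Xc, _ = build_design(df, covariates)
    X = np.column_stack([np.ones(len(df)), Xe, Xc]) if Xc.size else np.column_stack([np.ones(len(df)), Xe])
    res = sm.OLS(df[outcome].to_numpy(float), X).fit()
    return float(res.params[1]), float(res.pvalues[1])


def baron_kenny_conditions(
    df: pd.DataFrame,
    exposure: str,
    mediator: str,
    adjustment="mediation",
    duration_col: str = "time",
    event_col: str = "event",
    alpha: float = 0.05,
) -> BaronKennyReport:
    """Evaluate the four mediation preconditions and return the fitted paths."""
    covars = _resolve_adjustment(adjustment, df)
    a, a_p = _ols_path(df, mediator, exposure, covars)
    fit_c = fit_ph(df, exposure, adjustment, duration_col, event_col)
    c = float(fit_c.result.coef[fit_c._idx(exposure)])
    c_p = fit_c.p_value(exposure)
    fit_b = fit_ph(df, mediator, adjustment, duration_col, event_col)
    b_marg = float(fit_b.result.coef[fit_b._idx(mediator)])
    b_marg_p = fit_b.p_value(mediator)
    fit_full = fit_ph(df, [exposure, mediator], adjustment, duration_col, event_col)
    c_prime = float(fit_full.result.coef[fit_full._idx(exposure)])
    c_prime_p = fit_full.p_value(exposure)
    b = float(fit_full.result.coef[fit_full._idx(mediator)])
    conditions = {
        "exposure_affects_mediator": a_p < alpha,
        "exposure_affects_outcome": c_p < alpha,
        "mediator_affects_outcome": b_marg_p < alpha,
        "attenuation": abs(c_prime) < abs(c),
    }
    return BaronKennyReport(a=a, a_p=a_p, c=c, c_p=c_p, b_marginal=b_marg,
                            b_marginal_p=b_marg_p, b=b, c_prime=c_prime,
                            c_prime_p=c_prime_p, conditions=conditions)


@dataclass
class MediationResult:
    """Product-method mediation decomposition with bootstrap CIs."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    direct: float
    proportion: float
    proportion_alt: float          # 1 - c'/c
    B: int
    indirect_ci: tuple | None = None
    direct_ci: tuple | None = None
    proportion_ci: tuple | None = None
    sign_discordant: bool = False
    conditions: dict = field(default_factory=dict)


def _point_paths(df, exposure, mediator, adjustment, duration_col, event_col):
    covars = _resolve_adjustment(adjustment, df)
    a, _ = _ols_path(df, mediator, exposure, covars)
    fit_c = fit_ph(df, exposure, adjustment, duration_col, event_col)
    c = float(fit_c.result.coef[fit_c._idx(exposure)])
    fit_full = fit_ph(df, [exposure, mediator], adjustment, duration_col, event_col)
    c_prime = float(fit_full.result.coef[fit_full._idx(exposure)])
    b = float(fit_full.result.coef[fit_full._idx(mediator)])
    return a, b, c, c_prime


def mediation_effects(
    df: pd.DataFrame,
    exposure: str,
    mediator: str,
    adjustment="mediation",
    duration_col: str = "time",
    event_col: str = "event",
    B: int = 1000,
    seed: int | None = None,
    check_conditions: bool = True,
) -> MediationResult:
    """Point estimates and percentile-bootstrap CIs for the mediation paths.

    Resamples subjects with replacement and refits every path per replicate.
    ``B=1`` (or 0) skips interval estimation; point estimates are identical to
    the non-bootstrap path by construction.
    """
    conditions = {}
    if check_conditions:
        report = baron_kenny_conditions(df, exposure, mediator, adjustment,
                                        duration_col, event_col)
        conditions = report.conditions
        if not report.all_met:
            warnings.warn(f"Baron-Kenny conditions not all met: {conditions}", RuntimeWarning)

    a, b, c, c_prime = _point_paths(df, exposure, mediator, adjustment,
                                    duration_col, event_col)
    indirect = a * b
    direct = c_prime
    discordant = indirect * direct < 0
    if discordant:
        warnings.warn("indirect and direct effects have opposite signs; "
                      "the mediated proportion is ill-defined", RuntimeWarning)
    denom = indirect + direct
    proportion = indirect / denom if denom != 0 else np.nan
    proportion_alt = 1.0 - c_prime / c if c != 0 else np.nan

    ie_ci = de_ci = pr_ci = None
    if B >= 2:
        if seed is None:
            raise ValueError("seed is required for the bootstrap")
        rng = np.random.default_rng(seed)
        n = len(df)
        ies = np.empty(B)
        des = np.empty(B)
        prs = np.empty(B)
        for rep in range(B):
            idx = rng.integers(0, n, size=n)
            boot = df.iloc[idx].reset_index(drop=True)
            ab, bb, _, cpb = _point_paths(boot, exposure, mediator, adjustment,
                                          duration_col, event_col)
            ies[rep] = ab * bb
            des[rep] = cpb
            tot = ab * bb + cpb
            prs[rep] = ab * bb / tot if tot != 0 else np.nan
        qs = [2.5, 97.5]
        ie_ci = tuple(np.percentile(ies, qs))
        de_ci = tuple(np.percentile(des, qs))
        pr_ci = tuple(np.nanpercentile(prs, qs)) if not discordant else None
    elif B == 1:
        warnings.warn("B=1: confidence intervals are degenerate and omitted", RuntimeWarning)

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=indirect, direct=direct,
        proportion=float(proportion), proportion_alt=float(proportion_alt),
        B=B, indirect_ci=ie_ci, direct_ci=de_ci, proportion_ci=pr_ci,
        sign_discordant=bool(discordant), conditions=conditions,
    )
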