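"""Newton-Raphson solver for the Cox proportional-hazards partial likelihood.

Fully vectorized (no per-risk-set Python loop), Efron handling of tied event
times, covariance from the inverse observed information.  The O(n p^2) work per
iteration is three dense matrix products, which keeps large simulation studies
(n in the 10^5 range, hundreds of refits) tractable on a single core.

The algebraic trick: writing the information matrix as

    sum_{g,l} S2_gl / S0_gl  -  sum_{g,l} u_gl u_gl'

the first term collapses, after swapping the order of summation, to
X' diag(w * c) X where c_j accumulates 1/S0_gl over the event-time groups
whose risk set contains subject j (with the Efron l/d discount applied to the
tied-death rows).  Cross-checked against lifelines in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails."""


@dataclass
class CoxResult:
    """Maximum partial-likelihood fit of a Cox proportional-hazards model."""

    coef: np.ndarray            # log hazard ratios
    cov: np.ndarray             # inverse observed information
    loglik: float
    n: int
    n_events: int
    names: list[str] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, alpha: float = 0.05) -> np.ndarray:
        """Hazard-ratio confidence limits, shape (p, 2)."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.coef - z * self.se)
        hi = np.exp(self.coef + z * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def wald_test(self, idx) -> float:
        """Joint Wald chi-square p-value for the coefficients at ``idx``."""
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        b = self.coef[idx]
        V = self.cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(chi2, df=idx.size))


def _loglik_parts(X, t, e, beta, first_evt, d, lod, start, uniq):
    """Log partial likelihood, gradient and information at ``beta``."""
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = X * w[:, None]

    # suffix (risk-set) sums over ascending time order
    S0s = np.cumsum(w[::-1])[::-1]
    S1s = np.cumsum(wX[::-1], axis=0)[::-1]
    S0g = S0s[start]
    S1g = S1s[start]

    Xe = X[e]
    we = w[e]
    wXe = wX[e]
    S0D = np.add.reduceat(we, first_evt)
    S1D = np.add.reduceat(wXe, first_evt, axis=0)

    dd = d  # deaths per group
    S0gl = np.repeat(S0g, dd) - lod * np.repeat(S0D, dd)
    S1gl = np.repeat(S1g, dd, axis=0) - lod[:, None] * np.repeat(S1D, dd, axis=0)

    loglik = float(eta[e].sum() - np.log(S0gl).sum())
    U = S1gl / S0gl[:, None]
    grad = Xe.sum(axis=0) - U.sum(axis=0)

    inv = 1.0 / S0gl
    r_g = np.add.reduceat(inv, first_evt)          # sum_l 1/S0_gl per group
    cum_r = np.cumsum(r_g)
    gidx = np.searchsorted(uniq, t, side="right")  # groups with t_g <= t_j
    a = np.where(gidx > 0, cum_r[np.maximum(gidx - 1, 0)], 0.0)
    b_g = np.add.reduceat(lod * inv, first_evt)    # sum_l (l/d)/S0_gl per group
    c = a.copy()
    c[e] -= np.repeat(b_g, dd)                     # Efron discount on tied deaths

    H = X.T @ (X * (w * c)[:, None]) - U.T @ U     # observed information
    return loglik, grad, H


def cox_newton(
    X,
    time,
    event,
    names: list[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> CoxResult:
    """Fit a Cox model by Newton-Raphson on the Efron partial likelihood.

    Parameters
    ----------
    X : (n, p) array of covariates.
    time : (n,) follow-up times, > 0.
    event : (n,) event indicator in {0, 1}.
    ridge : optional small L2 penalty (stabilizes near-separated designs);
        zero by default so estimates are the plain MPLE.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event length mismatch with X")
    if not np.all(time > 0):
        raise ValueError("follow-up times must be positive")
    n_events = int(np.asarray(event, dtype=int).sum())
    if n_events < 1:
        raise ValueError("at least one event is required")

    order = np.argsort(time, kind="stable")
    Xs = X[order]
    t = time[order]
    e = np.asarray(event, dtype=bool)[order]

    xbar = Xs.mean(axis=0)
    xsd = Xs.std(axis=0)
    if np.any(xsd == 0):
        zero = [names[i] for i in np.flatnonzero(xsd == 0)]
        raise ValueError(f"constant covariate(s): {zero}")
    Xc = Xs - xbar

    te = t[e]
    uniq, first_evt, d = np.unique(te, return_index=True, return_counts=True)
    start = np.searchsorted(t, uniq, side="left")
    l_within = np.arange(te.size) - np.repeat(first_evt, d)
    lod = l_within / np.repeat(d, d).astype(float)

    beta = np.zeros(p)
    loglik, grad, H = _loglik_parts(Xc, t, e, beta, first_evt, d, lod, start, uniq)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Hp = H + ridge * np.eye(p) if ridge else H
        try:
            step = np.linalg.solve(Hp, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix (collinear or separated design)") from exc
        # step-halving line search on the log partial likelihood
        shrink = 1.0
        for _ in range(30):
            cand = beta + shrink * step
            ll_new, g_new, H_new = _loglik_parts(Xc, t, e, cand, first_evt, d, lod, start, uniq)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            shrink *= 0.5
        else:
            raise ConvergenceError("line search failed")
        delta = cand - beta
        beta, loglik, grad, H = cand, ll_new, g_new, H_new
        if np.max(np.abs(delta)) < tol or np.max(np.abs(grad)) < 1e-7:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    if np.max(np.abs(beta)) > 50:
        raise ConvergenceError("diverging coefficients: likely complete separation")

    cov = np.linalg.inv(H + ridge * np.eye(p) if ridge else H)
    return CoxResult(
        coef=beta,
        cov=cov,
        loglik=loglik,
        n=n,
        n_events=n_events,
        names=list(names),
        n_iter=it,
        converged=converged,
    )
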