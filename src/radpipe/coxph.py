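"""Cox proportional-hazards fitting by Newton iteration on the partial
likelihood, with Efron (default) or Breslow handling of tied event times.

This lean solver exists because the bootstrap wrapper-forward selection
protocol performs tens of thousands of small Cox fits; it is fully
vectorized over risk sets and returns the coefficient vector together
with the observed-information covariance for Wald inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "fit_cox"]


class CoxConvergenceError(RuntimeError):
    """Newton iterations failed to converge (e.g. monotone likelihood)."""


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    ties: str

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def hr_ci(self, alpha: float = 0.05) -> np.ndarray:
        """Hazard ratios with Wald (log-scale) confidence limits,
        shape (p, 3): HR, lower, upper."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = np.exp(self.coef - z * self.se)
        hi = np.exp(self.coef + z * self.se)
        return np.column_stack([self.hazard_ratios, lo, hi])


class _CoxData:
    """Precomputed, beta-independent structure of one Cox problem:
    rows sorted by decreasing time, tied-time block boundaries, and the
    Efron fraction l/d for every (event time, l) term."""

    def __init__(self, x, time, event, ties):
        order = np.argsort(-time, kind="stable")
        self.x = x[order]
        self.e = event[order].astype(bool)
        t_s = time[order]
        n = len(t_s)
        self.starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
        block_of_row = np.cumsum(np.r_[True, t_s[1:] != t_s[:-1]]) - 1
        d = np.bincount(block_of_row[self.e], minlength=len(self.starts))
        eb = np.flatnonzero(d)
        self.rep_b = np.repeat(eb, d[eb])
        if ties == "efron":
            self.fracs = np.concatenate(
                [np.arange(k) / k for k in d[eb]]) if len(eb) else np.empty(0)
        else:
            self.fracs = np.zeros(len(self.rep_b))
        # outer products x_i x_i^T per row, reused every evaluation
        self.xx = self.x[:, :, None] * self.x[:, None, :]
        self.x_ev_sum = self.x[self.e].sum(axis=0)


def _loglik_grad_hess(beta, data: _CoxData):
    """Partial log-likelihood, gradient and Hessian, fully vectorized
    over risk sets (Efron or Breslow per the precomputed fractions)."""
    x, e = data.x, data.e
    eta = x @ beta
    # cap to avoid overflow in exp during aggressive Newton steps
    w = np.exp(np.clip(eta, -200, 200))
    xw = x * w[:, None]
    xxw = data.xx * w[:, None, None]

    starts = data.starts
    rs_w = np.cumsum(np.add.reduceat(w, starts))
    rs_xw = np.cumsum(np.add.reduceat(xw, starts, axis=0), axis=0)
    rs_xxw = np.cumsum(np.add.reduceat(xxw, starts, axis=0), axis=0)

    we = np.where(e, w, 0.0)
    d_w = np.add.reduceat(we, starts)
    d_xw = np.add.reduceat(np.where(e[:, None], xw, 0.0), starts, axis=0)
    d_xxw = np.add.reduceat(np.where(e[:, None, None], xxw, 0.0),
                            starts, axis=0)

    b, f = data.rep_b, data.fracs
    denom = rs_w[b] - f * d_w[b]
    if np.any(denom <= 0):
        return -np.inf, None, None
    ll = float(eta[e].sum() - np.log(denom).sum())
    gbar = (rs_xw[b] - f[:, None] * d_xw[b]) / denom[:, None]
    grad = data.x_ev_sum - gbar.sum(axis=0)
    hnum = (rs_xxw[b] - f[:, None, None] * d_xxw[b]) / denom[:, None, None]
    hess = -(hnum.sum(axis=0) - gbar.T @ gbar)
    return ll, grad, hess


def fit_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
            ties: str = "efron", tol: float = 1e-7, max_iter: int = 60
            ) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    x : ndarray (n, p)
        Covariate matrix.
    time, event : ndarray (n,)
        Follow-up times and event indicators (1 = event, 0 = censored).
    ties : {"efron", "breslow"}
        Tied-event-time correction.
    tol : float
        Convergence threshold on the gradient max-norm.

    Raises
    ------
    CoxConvergenceError
        On non-convergence or a singular information matrix (e.g. perfect
        separation or a constant covariate).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.size > 1 and np.asarray(time).size != 1:
        x = x.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = x.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event must match the number of rows of x")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    n_events = int(event.sum())
    if n_events < p + 1:
        raise ValueError(f"need at least p+1={p + 1} events, got {n_events}")

    data = _CoxData(x, time, event, ties)
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, data)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}")
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(beta_new, data)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise CoxConvergenceError("line search failed")
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            try:
                cov = np.linalg.inv(-hess)
            except np.linalg.LinAlgError as exc:
                raise CoxConvergenceError(f"singular information at optimum: {exc}")
            return CoxFit(beta, cov, float(ll), it, ties)
    raise CoxConvergenceError(
        f"no convergence in {max_iter} iterations (|grad|={np.max(np.abs(grad)):.2e}); "
        "possible separation or monotone likelihood")
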