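"""Cox proportional-hazards internals shared by the DE screens and the signature fit.

Everything here works on the Breslow approximation to the partial likelihood:
tied event times all see the full risk set. The module exposes

* :func:`breslow_loglik` — log partial likelihood at a linear predictor,
* :func:`breslow_eta_derivatives` — per-subject first/second derivatives with
  respect to the linear predictor (the IRLS working quantities for the lasso),
* :func:`cox_newton` — safeguarded Newton maximization of the joint model.
"""

from __future__ import annotations

import numpy as np

from .errors import ConvergenceError, NoEventsError

__all__ = [
    "breslow_loglik",
    "breslow_eta_derivatives",
    "BreslowWorkspace",
    "cox_newton",
    "CoxFit",
]


def _risk_order(time: np.ndarray):
    """Ascending time order plus, per subject, the first index of its tie group."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    n = len(t_sorted)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = t_sorted[1:] != t_sorted[:-1]
    first = np.maximum.accumulate(np.where(change, np.arange(n), 0))
    return order, t_sorted, first


class BreslowWorkspace:
    """Precomputed sort/tie structure for repeated likelihood evaluations on
    one (time, event) sample — the hot path of the penalized fits."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.n = len(time)
        self.order, _, self.first = _risk_order(np.asarray(time, dtype=float))
        self.d_sorted = np.asarray(event, dtype=float)[self.order]
        self.group_starts = np.unique(self.first)
        self.deaths_in_group = np.add.reduceat(self.d_sorted, self.group_starts)
        self.group_idx = np.searchsorted(self.group_starts, self.first, side="right") - 1

    def loglik(self, eta: np.ndarray) -> float:
        eta_s = eta[self.order]
        r = np.exp(eta_s)
        s0 = np.cumsum(r[::-1])[::-1][self.first]
        return float(np.sum(self.d_sorted * (eta_s - np.log(s0))))

    def derivatives(self, eta: np.ndarray):
        """(loglik, g, h): per-subject first derivative and (diagonal) negative
        second derivative of the partial likelihood in the linear predictor."""
        eta_s = eta[self.order]
        r = np.exp(eta_s)
        rev = np.cumsum(r[::-1])[::-1]
        s0 = rev[self.first]
        s0_group = rev[self.group_starts]
        # accumulate d_s / S0 and d_s / S0^2 over event times <= t_i
        a = np.cumsum(self.deaths_in_group / s0_group)[self.group_idx]
        b = np.cumsum(self.deaths_in_group / s0_group**2)[self.group_idx]
        g_sorted = self.d_sorted - r * a
        h_sorted = r * a - r**2 * b
        ll = float(np.sum(self.d_sorted * (eta_s - np.log(s0))))
        g = np.empty(self.n)
        h = np.empty(self.n)
        g[self.order] = g_sorted
        h[self.order] = h_sorted
        return ll, g, h


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    return BreslowWorkspace(time, event).loglik(np.asarray(eta, dtype=float))


def breslow_eta_derivatives(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Per-subject gradient ``g_i = d ll / d eta_i`` and curvature ``h_i = -d2 ll / d eta_i^2``.

    Uses the diagonal of the Hessian in eta (the standard glmnet-style
    approximation). Returns (loglik, g, h) in the original subject order.
    """
    return BreslowWorkspace(time, event).derivatives(np.asarray(eta, dtype=float))


def _loglik_grad_hess(beta, X, time, event):
    """Full gradient and Hessian of the Breslow partial likelihood in beta."""
    order, _, first = _risk_order(time)
    Xs = X[order]
    d_s = event[order].astype(bool)
    eta_s = Xs @ beta
    r = np.exp(eta_s)

    rx = r[:, None] * Xs
    rxx = np.einsum("i,ij,ik->ijk", r, Xs, Xs)
    s0 = np.cumsum(r[::-1])[::-1][first]
    s1 = np.cumsum(rx[::-1], axis=0)[::-1][first]
    s2 = np.cumsum(rxx[::-1], axis=0)[::-1][first]

    ll = float(np.sum(eta_s[d_s] - np.log(s0[d_s])))
    mean = s1 / s0[:, None]
    grad = np.sum(Xs[d_s] - mean[d_s], axis=0)
    cov = s2 / s0[:, None, None] - np.einsum("ij,ik->ijk", mean, mean)
    neg_hess = np.sum(cov[d_s], axis=0)
    return ll, grad, neg_hess


class CoxFit:
    """Converged Cox fit: coefficients, standard errors and diagnostics."""

    def __init__(self, beta, se, loglik, loglik_null, iterations):
        self.beta = beta
        self.se = se
        self.loglik = loglik
        self.loglik_null = loglik_null
        self.iterations = iterations


def cox_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Breslow partial likelihood by Newton iteration with step halving.

    Raises :class:`NoEventsError` when no event is observed and
    :class:`ConvergenceError` (carrying the last iterate) past ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if event.sum() == 0:
        raise NoEventsError("cannot fit a Cox model with zero observed events")

    p = X.shape[1]
    beta = np.zeros(p)
    ll_null = breslow_loglik(X @ beta, time, event)
    ll = ll_null
    for it in range(1, max_iter + 1):
        ll, grad, neg_hess = _loglik_grad_hess(beta, X, time, event)
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            cov = np.linalg.inv(neg_hess)
            return CoxFit(beta, np.sqrt(np.diag(cov)), ll, ll_null, it)
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(neg_hess, grad, rcond=None)[0]
        # step halving: never accept a decrease in the partial likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            if breslow_loglik(X @ cand, time, event) >= ll:
                break
            scale /= 2.0
        beta = beta + scale * step
    raise ConvergenceError(
        f"Cox Newton iteration did not converge in {max_iter} steps", last_iterate=beta
    )
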