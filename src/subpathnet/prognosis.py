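"""Prognostic signature over subpathway activities: batch merging, l1-penalized
Cox fitting, risk scoring and survival evaluation.

The signature model is an l1-penalized (lasso) Cox proportional-hazards fit on
the subpathway x sample NES matrix:

    minimize  -(1/n) * Breslow partial log-likelihood(X beta)  +  lambda * ||beta||_1

solved by iteratively reweighted least squares with cyclic coordinate descent
on the quadratic surrogate, warm-started along a decreasing lambda grid
(100 points, four decades down from lambda_max). lambda is selected by k-fold
cross-validated partial-likelihood deviance (Verweij & van Houwelingen form);
the subpathways with non-zero coefficients at the selected lambda are the
signature. Activities are standardized to unit variance before penalization
and coefficients are reported on the original scale. The per-sample risk score
is the linear predictor; cohorts are split at the training-set median score
and compared by Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numba
import numpy as np
import pandas as pd
from scipy import stats

from ._cox import BreslowWorkspace, breslow_eta_derivatives, breslow_loglik, cox_newton
from .diffexpr import CoxResult, _classify
from .errors import (
    AlignmentError,
    CollinearityError,
    InvalidArgumentError,
    NoEventsError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "LassoModel",
    "RiskScore",
    "batch_merge",
    "lasso_survival_fit",
    "risk_score_and_split",
    "km_logrank",
    "multivariate_cox",
]


@dataclass
class SurvivalCohort:
    """Per-sample follow-up time, event indicator and clinical covariates."""

    data: pd.DataFrame  # index: sample; columns: time, event, covariates...

    def __post_init__(self):
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise InvalidArgumentError(f"survival table must have a {col!r} column")
        if (self.data["time"] <= 0).any():
            raise InvalidArgumentError("survival times must be positive")
        if not self.data["event"].isin((0, 1)).all():
            raise InvalidArgumentError("event indicator must be 0/1")

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, samples: Sequence) -> "SurvivalCohort":
        return SurvivalCohort(self.data.loc[list(samples)])


# ---------------------------------------------------------------------------
# batch merging


def batch_merge(studies: Iterable, batch_key: str = "dataset") -> pd.DataFrame:
    """Merge expression studies into one matrix with batch effects removed.

    Genes are intersected across studies, values put on the log2 scale, and
    per-gene location/scale batch parameters are shrunk with the parametric
    empirical-Bayes ComBat scheme (one batch per study). With a single study
    the input is returned on the common gene space unchanged — there is no
    batch to adjust.
    """
    studies = list(studies)
    if not studies:
        raise InvalidArgumentError("no studies supplied")
    shared = set(studies[0].values.index)
    for s in studies[1:]:
        shared &= set(s.values.index)
    if not shared:
        raise InvalidArgumentError("studies share no genes")
    shared = sorted(shared)
    frames = [s.log_values().loc[shared] for s in studies]
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        raise InvalidArgumentError("duplicate sample ids across studies")
    if len(studies) == 1:
        return merged
    for s in studies:
        if s.values.shape[1] < 3:
            raise InvalidArgumentError(
                f"batch {s.dataset_id!r} has fewer than 3 samples"
            )
    batches = np.concatenate(
        [[s.dataset_id] * s.values.shape[1] for s in studies]
    )
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=merged.to_numpy(dtype=float).T,
        obs=pd.DataFrame({batch_key: batches}, index=merged.columns),
        var=pd.DataFrame(index=merged.index),
    )
    sc.pp.combat(adata, key=batch_key)
    return pd.DataFrame(adata.X.T, index=merged.index, columns=merged.columns)


# ---------------------------------------------------------------------------
# l1-penalized Cox


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, sd, sd_safe


@numba.njit(cache=False)
def _cd_quadratic(X, wX, wx2, resid, beta, lam, n, inner_tol):  # pragma: no cover
    """Cyclic coordinate descent on the weighted-least-squares surrogate
    (1/2n) sum w (z - X beta)^2 + lam ||beta||_1, with the usual active-set
    cycling: iterate the non-zero set to convergence, then one full sweep to
    admit new coordinates. Updates ``resid`` and ``beta`` in place."""
    nrows, p = X.shape
    for _cycle in range(1000):
        # converge on the current active (non-zero) set
        for _inner in range(1000):
            max_delta = 0.0
            for j in range(p):
                if beta[j] == 0.0 or wx2[j] <= 0.0:
                    continue
                rho = 0.0
                for i in range(nrows):
                    rho += wX[i, j] * resid[i]
                rho = rho / n + wx2[j] * beta[j]
                mag = abs(rho) - lam
                bj = (mag / wx2[j]) * (1.0 if rho > 0 else -1.0) if mag > 0 else 0.0
                delta = bj - beta[j]
                if delta != 0.0:
                    for i in range(nrows):
                        resid[i] -= X[i, j] * delta
                    beta[j] = bj
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if max_delta < inner_tol:
                break
        # full sweep over all coordinates
        max_delta = 0.0
        for j in range(p):
            if wx2[j] <= 0.0:
                continue
            rho = 0.0
            for i in range(nrows):
                rho += wX[i, j] * resid[i]
            rho = rho / n + wx2[j] * beta[j]
            mag = abs(rho) - lam
            bj = (mag / wx2[j]) * (1.0 if rho > 0 else -1.0) if mag > 0 else 0.0
            delta = bj - beta[j]
            if delta != 0.0:
                for i in range(nrows):
                    resid[i] -= X[i, j] * delta
                beta[j] = bj
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < inner_tol:
            break


def lasso_cox_objective(beta, X, time, event, lam) -> float:
    """Penalized objective -(1/n) loglik + lam * ||beta||_1 (standardized scale)."""
    n = len(time)
    return -breslow_loglik(X @ beta, time, event) / n + lam * np.abs(beta).sum()


def lambda_max(X, time, event) -> float:
    """Smallest penalty at which the lasso path is entirely zero: the largest
    absolute per-covariate score gradient of the null model, on the 1/n scale."""
    n = len(time)
    _, g, _ = breslow_eta_derivatives(np.zeros(n), time, event)
    return float(np.max(np.abs(X.T @ g)) / n)


def _coordinate_descent_fit(
    X, time, event, lam, beta0, outer_max=100, outer_tol=1e-8, inner_tol=1e-9,
    kkt_tol=1e-8, objective_trace=None, workspace=None,
):
    """One lasso-Cox solve at a fixed penalty by IRLS + cyclic coordinate descent.

    The inner solver cycles over the active (non-zero) set until stable, then
    runs one full sweep to admit new coordinates, in the usual glmnet pattern.
    The outer loop stops when the subgradient optimality conditions hold to
    ``kkt_tol``. A step-halving safeguard keeps the true penalized objective
    non-increasing across outer sweeps; the objective after each outer sweep
    is appended to ``objective_trace`` when supplied.
    """
    n, p = X.shape
    ws = workspace if workspace is not None else BreslowWorkspace(time, event)
    beta = beta0.copy()

    def objective(b):
        return -ws.loglik(X @ b) / n + lam * np.abs(b).sum()

    obj = objective(beta)
    for _ in range(outer_max):
        eta = X @ beta
        _, g, h = ws.derivatives(eta)
        grad = X.T @ g / n
        viol = np.where(
            beta != 0.0, np.abs(grad - lam * np.sign(beta)), np.maximum(np.abs(grad) - lam, 0.0)
        )
        if np.max(viol) < kkt_tol:
            break
        w = np.maximum(h, 1e-9)
        z = eta + g / w
        wX = np.asfortranarray(X * w[:, None])
        wx2 = (wX * X).sum(axis=0) / n
        beta_new = beta.copy()
        resid = z - X @ beta_new
        _cd_quadratic(np.asfortranarray(X), wX, wx2, resid, beta_new,
                      float(lam), float(n), inner_tol)
        # safeguard: halve the step until the true objective does not increase
        step = beta_new - beta
        scale = 1.0
        obj_new = objective(beta + step)
        for _ in range(30):
            if obj_new <= obj + 1e-12:
                break
            scale /= 2.0
            obj_new = objective(beta + scale * step)
        beta = beta + scale * step
        moved = float(np.max(np.abs(scale * step))) if p else 0.0
        obj = min(obj, obj_new)
        if objective_trace is not None:
            objective_trace.append(obj)
        if moved < outer_tol:
            break
    return beta


def lasso_cox_path(X, time, event, lambdas, objective_trace=None,
                   dev_ratio_max: float = 0.999):
    """Warm-started coefficient path over a decreasing lambda grid
    (standardized covariates); returns an array of shape (len(lambdas), p).

    The path stops early once the model approaches saturation (fraction of
    null deviance explained above ``dev_ratio_max``, reachable only when the
    predictors can nearly separate the event order, as in p >= n fits);
    remaining grid rows repeat the last solution.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise InvalidArgumentError("lambda grid must be non-increasing")
    n, p = X.shape
    ws = BreslowWorkspace(np.asarray(time, float), np.asarray(event, float))
    ll_null = ws.loglik(np.zeros(n))
    ll_sat = 0.0  # Breslow saturated partial likelihood bound
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _coordinate_descent_fit(
            X, time, event, lam, beta, objective_trace=objective_trace, workspace=ws
        )
        betas[i] = beta
        ll = ws.loglik(X @ beta)
        denom = ll_sat - ll_null
        dev_ratio = (ll - ll_null) / denom if denom != 0 else 0.0
        if dev_ratio > dev_ratio_max:
            betas[i + 1:] = beta
            break
    return betas


def lasso_kkt_violation(beta, X, time, event, lam) -> float:
    """Maximum violation of the subgradient optimality conditions at ``beta``."""
    n = len(time)
    _, g, _ = breslow_eta_derivatives(X @ beta, time, event)
    grad = X.T @ g / n  # gradient of +(1/n) loglik
    viol = 0.0
    for j in range(len(beta)):
        if beta[j] != 0.0:
            viol = max(viol, abs(grad[j] - lam * np.sign(beta[j])))
        else:
            viol = max(viol, max(abs(grad[j]) - lam, 0.0))
    return float(viol)


@dataclass
class LassoModel:
    """Sparse Cox signature: non-zero coefficients on the original activity scale."""

    coefficients: dict[str, float]
    lambda_grid: np.ndarray
    selected_lambda: float
    cv_deviance: np.ndarray
    training_median: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def subpathways(self) -> list[str]:
        return list(self.coefficients)


def _cv_fold_labels(n, cv_folds, rng):
    labels = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(labels)
    return labels


def lasso_survival_fit(
    activity,
    cohort: SurvivalCohort,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> LassoModel:
    """Fit the lasso Cox signature with cross-validated penalty selection.

    ``activity`` is an ActivityMatrix or subpathway x sample DataFrame aligned
    with the cohort samples. The selected lambda minimizes the mean
    cross-validated partial-likelihood deviance
    -2 * [ll_all(beta_-k) - ll_train(beta_-k)] over the grid.
    """
    frame = activity if isinstance(activity, pd.DataFrame) else getattr(activity, "values", None)
    if not isinstance(frame, pd.DataFrame):
        raise InvalidArgumentError("activity must be an ActivityMatrix or DataFrame")
    samples = cohort.samples
    missing = [s for s in samples if s not in frame.columns]
    if missing:
        raise AlignmentError(f"activity matrix is missing cohort samples: {missing[:5]}")
    X_raw = frame[samples].to_numpy(dtype=float).T  # n x p
    time = cohort.time.to_numpy(dtype=float)
    event = cohort.event.to_numpy(dtype=float)
    if event.sum() == 0:
        raise NoEventsError("cohort has no observed events")
    X, sd, sd_safe = _standardize(X_raw)

    if lambda_grid is None:
        if lambda_min_ratio is None:
            # four decades when n > p; two when p >= n, where the unpenalized
            # end of the path is unbounded (the glmnet convention)
            lambda_min_ratio = 1e-4 if X.shape[0] > X.shape[1] else 1e-2
        lmax = lambda_max(X, time, event)
        lambda_grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    rng = np.random.default_rng(seed)
    folds = _cv_fold_labels(len(time), cv_folds, rng)
    n = len(time)
    cv_dev = np.zeros((cv_folds, len(lambda_grid)))
    ws_all = BreslowWorkspace(time, event)
    for k in range(cv_folds):
        train = folds != k
        ws_train = BreslowWorkspace(time[train], event[train])
        betas = lasso_cox_path(X[train], time[train], event[train], lambda_grid)
        for i, beta in enumerate(betas):
            cv_dev[k, i] = -2.0 * (ws_all.loglik(X @ beta) - ws_train.loglik(X[train] @ beta))
    mean_dev = cv_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    selected = float(lambda_grid[best])

    betas = lasso_cox_path(X, time, event, lambda_grid)
    beta_std = betas[best]
    beta_orig = beta_std / sd_safe
    coefficients = {
        sid: float(b)
        for sid, b, s in zip(frame.index, beta_orig, sd)
        if b != 0.0 and s > 0
    }
    if not coefficients:
        logger.warning("degenerate signature: every coefficient is zero at the selected lambda")
    return LassoModel(
        coefficients=coefficients,
        lambda_grid=lambda_grid,
        selected_lambda=selected,
        cv_deviance=mean_dev,
        metadata={
            "cv_folds": cv_folds,
            "cv_criterion": "partial_likelihood_deviance",
            "seed": seed,
            "standardized": True,
        },
    )


# ---------------------------------------------------------------------------
# risk scoring and survival evaluation


@dataclass
class RiskScore:
    scores: pd.Series
    groups: pd.Series  # "high" / "low"
    split_median: float
    degenerate: bool = False


def risk_score_and_split(
    model: LassoModel, activity, training_median: float | None = None
) -> RiskScore:
    """Per-sample linear predictor sum(coef * NES) and a high/low median split.

    Uses the supplied training median when given (for independent test
    cohorts), else this cohort's own median. An all-equal score vector is
    flagged as degenerate.
    """
    frame = activity if isinstance(activity, pd.DataFrame) else getattr(activity, "values", None)
    if not isinstance(frame, pd.DataFrame):
        raise InvalidArgumentError("activity must be an ActivityMatrix or DataFrame")
    missing = [sid for sid in model.coefficients if sid not in frame.index]
    if missing:
        raise AlignmentError(f"activity matrix is missing signature subpathways: {missing}")
    if model.coefficients:
        coef = pd.Series(model.coefficients)
        scores = frame.loc[coef.index].T @ coef
    else:
        scores = pd.Series(0.0, index=frame.columns)
    scores.name = "risk_score"
    median = float(np.median(scores)) if training_median is None else float(training_median)
    degenerate = bool(np.all(scores.to_numpy() == scores.iloc[0]))
    if degenerate:
        logger.warning("risk scores are constant; the high/low split is degenerate")
    groups = pd.Series(np.where(scores > median, "high", "low"), index=scores.index, name="risk_group")
    return RiskScore(scores=scores, groups=groups, split_median=median, degenerate=degenerate)


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # per group: time, survival
    statistic: float
    p_value: float


def km_logrank(cohort: SurvivalCohort, groups) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""
    groups = pd.Series(groups, index=cohort.samples) if not isinstance(groups, pd.Series) else groups
    groups = groups.loc[cohort.samples]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise InvalidArgumentError("log-rank comparison needs two non-empty groups")
    if len(levels) > 2:
        raise InvalidArgumentError(f"expected two groups, got {levels}")
    if cohort.event.sum() == 0:
        raise NoEventsError("no events observed")

    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    curves = {}
    for level in levels:
        mask = (groups == level).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.time[mask], cohort.event[mask], label=str(level))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(level)] = sf
    mask = (groups == levels[0]).to_numpy()
    res = logrank_test(
        cohort.time[mask], cohort.time[~mask],
        event_observed_A=cohort.event[mask], event_observed_B=cohort.event[~mask],
    )
    return KMResult(curves=curves, statistic=float(res.test_statistic), p_value=float(res.p_value))


def multivariate_cox(
    cohort: SurvivalCohort,
    covariates: pd.DataFrame,
    p_threshold: float = 0.05,
) -> dict[str, CoxResult]:
    """Joint Cox fit over a covariate matrix (risk score, grade, age, ...).

    Raises :class:`CollinearityError` naming the offending columns when the
    matrix is rank deficient.
    """
    covariates = covariates.loc[cohort.samples]
    X = covariates.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise InvalidArgumentError("no covariates supplied")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        # name columns whose residual norm after projecting on the others is ~0
        offending = []
        q, r = np.linalg.qr(centered)
        diag = np.abs(np.diag(r))
        tol = diag.max() * 1e-10 if diag.max() > 0 else 1e-10
        for j, d in enumerate(diag):
            if d < tol:
                offending.append(covariates.columns[j])
        raise CollinearityError(
            f"covariate matrix is rank deficient (rank {rank} < {X.shape[1]})",
            columns=offending or list(covariates.columns),
        )
    fit = cox_newton(X, cohort.time.to_numpy(float), cohort.event.to_numpy(float))
    out = {}
    for j, name in enumerate(covariates.columns):
        log_hr, se = float(fit.beta[j]), float(fit.se[j])
        z = log_hr / se if se > 0 else np.inf * np.sign(log_hr)
        p = float(2 * stats.norm.sf(abs(z)))
        hr = float(np.exp(log_hr))
        out[name] = CoxResult(covariate=name, log_hr=log_hr, hr=hr, p_value=p,
                              classification=_classify(hr, p, p_threshold), se=se)
    return out
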