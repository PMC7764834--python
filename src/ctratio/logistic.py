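"""Class-balanced logistic regression and leave-one-out cross-validation.

The classifier is plain binary logistic regression with an intercept,
maximising a *weighted* log-likelihood in which each sample carries weight
N / (2 * n_class), so the two comparison groups contribute equal total
weight regardless of their sizes (inverse-frequency balancing).  Fitting is
Newton/IRLS to a gradient-norm tolerance of 1e-8 with at most 100
iterations; under complete separation the likelihood has no maximiser, so
the last iterate is returned with ``converged=False`` — its predictions
saturate toward 0/1 on the correct sides, which is exactly what the
cross-validation loop needs.

``loocv_predict`` refits the model N times, each time without one sample
and with the balancing weights recomputed on that training fold, and
records the held-out sample's predicted probability.  The N Newton
recursions are run simultaneously (arrays shaped folds x coefficients),
which is algebraically identical to the per-fold loop (a test pins the
equality) but orders of magnitude faster inside the exhaustive model
search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-8
MAX_ITER = 100
_ETA_CLIP = 35.0  # |logit| beyond this is numerically saturated


@dataclass
class LogisticFit:
    """Fitted coefficients (intercept first) with convergence diagnostics."""

    coef: np.ndarray
    converged: bool
    n_iter: int

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coef[1:]


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.ravel(y)) != 1:
        X = X.T
    y = np.asarray(y).ravel().astype(float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y length mismatch")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite covariate value")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    return X, y


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """w_i = N / (2 * n_class(i)): each class totals N/2."""
    y = np.asarray(y, float).ravel()
    n = len(y)
    n1 = y.sum()
    n0 = n - n1
    return np.where(y == 1, n / (2.0 * n1), n / (2.0 * n0))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def fit_weighted_logistic(X, y, balanced: bool = True,
                          sample_weight: np.ndarray | None = None,
                          tol: float = GRAD_TOL,
                          max_iter: int = MAX_ITER) -> LogisticFit:
    """Newton/IRLS fit of weighted logistic regression with intercept.

    ``balanced=True`` (default) applies inverse-frequency class weights;
    ``balanced=False`` with no ``sample_weight`` is the ordinary unweighted
    fit.  Returns the last iterate with ``converged=False`` if the gradient
    tolerance is not reached within ``max_iter`` iterations (separation).
    """
    X, y = _check_xy(X, y)
    if sample_weight is not None:
        w = np.asarray(sample_weight, float).ravel()
    elif balanced:
        w = balanced_weights(y)
    else:
        w = np.ones_like(y)

    Xa = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xa.shape[1])
    converged = False
    it = 0
    p_prev = None
    for it in range(1, max_iter + 1):
        eta = Xa @ beta
        p = _sigmoid(eta)
        grad = Xa.T @ (w * (y - p))
        if np.max(np.abs(grad)) < tol:
            # a saturated fit (all logits at the numerical ceiling) zeroes
            # the float gradient too; only an interior optimum counts as
            # converged
            converged = bool(np.max(np.abs(eta)) < _ETA_CLIP)
            break
        if p_prev is not None and np.max(np.abs(p - p_prev)) < 1e-14:
            # separation: every probability is numerically saturated, so
            # further Newton steps cannot change the fitted surface
            break
        p_prev = p
        s = w * p * (1.0 - p)
        hess = (Xa * s[:, None]).T @ Xa
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-10 * np.eye(hess.shape[0]), grad)
        beta = beta + step
    return LogisticFit(coef=beta, converged=converged, n_iter=it)


def predict_proba(fit: LogisticFit, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != len(fit.coef) - 1:
        X = X.T
    return _sigmoid(fit.coef[0] + X @ fit.coef[1:])


def loocv_predict(X, y, balanced: bool = True, tol: float = GRAD_TOL,
                  max_iter: int = MAX_ITER) -> np.ndarray:
    """Out-of-fold probability of class 1 for every sample.

    Deterministic: no randomness anywhere in the loop.  A fold whose
    training set loses its last member of a class cannot be fitted; its
    prediction is the balanced-weights prior 0.5 and a warning is logged.
    """
    X, y = _check_xy(X, y)
    n = len(y)
    if n < 3:
        raise ValidationError("leave-one-out needs at least 3 samples")
    n1 = y.sum()
    n0 = n - n1

    # per-fold class counts after removing the held-out sample
    n1_f = n1 - y
    n0_f = n0 - (1.0 - y)
    degenerate = (n1_f == 0) | (n0_f == 0)
    if degenerate.any():
        logger.warning("%d LOOCV folds lost a whole class; predicting 0.5",
                       int(degenerate.sum()))

    folds = np.flatnonzero(~degenerate)
    probs = np.full(n, 0.5)
    if folds.size == 0:
        return probs

    Xa = np.column_stack([np.ones(n), X])
    d = Xa.shape[1]
    m = folds.size
    # weight matrix: rows samples, cols folds; zero for the held-out sample
    if balanced:
        w1 = (n - 1) / (2.0 * n1_f[folds])
        w0 = (n - 1) / (2.0 * n0_f[folds])
        W = np.where(y[:, None] == 1, w1[None, :], w0[None, :])
    else:
        W = np.ones((n, m))
    W[folds, np.arange(m)] = 0.0

    # warm start every fold at the full-data fit: each training fold differs
    # from the full data by one observation, so one or two Newton steps
    # usually finish the job (the optimum reached is start-independent)
    full = fit_weighted_logistic(X, y, balanced=balanced, tol=tol,
                                 max_iter=max_iter)
    B = np.tile(full.coef, (m, 1))
    xx = (Xa[:, :, None] * Xa[:, None, :]).reshape(n, d * d)  # outer products
    active = np.arange(m)
    eye = np.eye(d)
    p_prev: np.ndarray | None = None
    for it in range(max_iter):
        Wa = W[:, active]
        P = _sigmoid(Xa @ B[active].T)            # samples x active folds
        R = Wa * (y[:, None] - P)
        G = R.T @ Xa                              # folds x d
        done = np.abs(G).max(axis=1) < tol
        if p_prev is not None:
            # under separation the likelihood has no maximiser and the
            # gradient never reaches tol; once every probability in a fold
            # is numerically saturated, further Newton steps are a no-op on
            # the output, so the fold can be frozen (same result as running
            # out the iteration cap, at a fraction of the cost)
            done |= np.abs(P - p_prev).max(axis=0) < 1e-14
        S = Wa * P * (1.0 - P)
        H = (S.T @ xx).reshape(-1, d, d)
        try:
            step = np.linalg.solve(H, G[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-10 * eye, G[..., None])[..., 0]
        B[active] += np.where(done[:, None], 0.0, step)
        active = active[~done]
        if active.size == 0:
            break
        p_prev = P[:, ~done]

    eta = np.einsum("fd,fd->f", Xa[folds], B)
    probs[folds] = _sigmoid(eta)
    return probs
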