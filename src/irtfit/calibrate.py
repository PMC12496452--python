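"""Bock--Aitkin EM estimation of the 2PL model with missing responses.

Marginal maximum likelihood over a fixed quadrature approximation of the
standard-normal population.  The E-step computes every person's normalized
posterior over the quadrature points (the unit pseudocounts) and accumulates
expected category counts per item (the E-table); the M-step maximizes each
item's expected complete-data binomial log-likelihood over the slope and
intercept by Newton iterations with step-halving.  Persons contribute only
their observed responses, so random missingness is handled by the likelihood
itself.

The item-parameter covariance matrix needed by the posterior-predictive
machinery is computed from the observed information of the marginal
log-likelihood.  The default method evaluates the information analytically
via Louis' identity (complete information minus missing information,
assembled from per-person posterior moments); a finite-difference Hessian
and an outer-product-of-gradients estimate are available behind the same
interface for cross-checking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit, logsumexp

from .data import ResponseMatrix
from .model import (
    ItemParams2PL,
    QuadratureGrid,
    arrays_to_params,
    make_grid,
    params_to_arrays,
    prob_matrix,
)

__all__ = [
    "CalibrationResult",
    "DegenerateItemError",
    "posterior_over_grid",
    "marginal_loglik",
    "fit_2pl",
    "param_covariance",
]

logger = logging.getLogger(__name__)


class DegenerateItemError(ValueError):
    """An item with no correct or no incorrect valid responses is inestimable."""


@dataclass
class CalibrationResult:
    """Outcome of an EM calibration run."""

    params: list[ItemParams2PL]
    loglik: float
    n_iter: int
    converged: bool
    grid: QuadratureGrid
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([p.slope for p in self.params])

    @property
    def difficulties(self) -> np.ndarray:
        return np.array([p.difficulty for p in self.params])


def _loglik_matrix(responses: ResponseMatrix, a, c, grid: QuadratureGrid) -> np.ndarray:
    """N x Q matrix of log prior + log conditional likelihood at each point."""
    z = np.outer(a, grid.points) + np.asarray(c, dtype=float)[:, None]
    u1, u0 = responses.indicator_arrays()
    ll = u1 @ log_expit(z) + u0 @ log_expit(-z)
    ll += np.log(grid.weights)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite likelihood contribution")
    return ll


def posterior_over_grid(responses: ResponseMatrix, params, grid: QuadratureGrid) -> np.ndarray:
    """Per-person normalized posterior weights over the quadrature points.

    Row ``j`` is proportional to the prior weight times the likelihood of
    person ``j``'s observed responses at each point, normalized to sum to
    one so every person has the same overall contribution.  A person with no
    valid responses gets the prior weights back.
    """
    a, c = params_to_arrays(params)
    if a.size != responses.n:
        raise ValueError("params length does not match item count")
    ll = _loglik_matrix(responses, a, c, grid)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    return post


def marginal_loglik(responses: ResponseMatrix, params, grid: QuadratureGrid) -> float:
    """Marginal log-likelihood (nats) of the responses under 2PL parameters."""
    a, c = params_to_arrays(params)
    return float(logsumexp(_loglik_matrix(responses, a, c, grid), axis=1).sum())


def _etable(responses: ResponseMatrix, post: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected correct/incorrect counts per item per quadrature point."""
    u1, u0 = responses.indicator_arrays()
    return u1.T @ post, u0.T @ post


def _mstep(r1, r0, points, a, c, max_newton=50):
    """Per-item Newton maximization of the expected complete-data log-likelihood."""
    a, c = a.copy(), c.copy()
    tot = r1 + r0

    def objective(a_, c_):
        z = np.outer(a_, points) + c_[:, None]
        return (r1 * log_expit(z) + r0 * log_expit(-z)).sum(axis=1)

    f_cur = objective(a, c)
    for _ in range(max_newton):
        z = np.outer(a, points) + c[:, None]
        p = 1.0 / (1.0 + np.exp(-z))
        resid = r1 - tot * p
        ga = resid @ points
        gc = resid.sum(axis=1)
        w = tot * p * (1.0 - p)
        haa = w @ points**2
        hac = w @ points
        hcc = w.sum(axis=1)
        if max(np.abs(ga).max(), np.abs(gc).max()) < 1e-9:
            break
        det = haa * hcc - hac**2
        det = np.where(det < 1e-12, 1e-12, det)
        da = (hcc * ga - hac * gc) / det
        dc = (haa * gc - hac * ga) / det
        # step-halving, also guarding the positivity of the slope
        step = np.ones_like(a)
        for _ in range(30):
            a_new = a + step * da
            c_new = c + step * dc
            bad = (a_new <= 1e-3) | (objective(a_new, c_new) < f_cur - 1e-12)
            if not bad.any():
                break
            step[bad] *= 0.5
        a, c = a + step * da, c + step * dc
        f_cur = objective(a, c)
    return a, c


def fit_2pl(
    responses: ResponseMatrix,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CalibrationResult:
    """Fit the 2PL model by the Bock--Aitkin EM algorithm.

    Convergence is declared when the largest absolute change of any slope or
    intercept between EM cycles falls below ``tol``.  The marginal
    log-likelihood is recorded each cycle and is nondecreasing.
    """
    grid = grid if grid is not None else make_grid()
    nv, nc = responses.n_valid, responses.n_correct
    degenerate = (nv == 0) | (nc == 0) | (nc == nv)
    if degenerate.any():
        bad = [responses.item_ids[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateItemError(
            f"items with all-correct, all-incorrect, or no valid responses: {bad}"
        )
    phat = np.clip(nc / nv, 0.02, 0.98)
    a = np.ones(responses.n)
    c = np.log(phat / (1.0 - phat))
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll = _loglik_matrix(responses, a, c, grid)
        path.append(float(logsumexp(ll, axis=1).sum()))
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        post /= post.sum(axis=1, keepdims=True)
        r1, r0 = _etable(responses, post)
        a_new, c_new = _mstep(r1, r0, grid.points, a, c)
        delta = max(np.abs(a_new - a).max(), np.abs(c_new - c).max())
        a, c = a_new, c_new
        if delta < tol:
            converged = True
            break
    loglik = marginal_loglik(responses, (a, c), grid)
    path.append(loglik)
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", RuntimeWarning)
    return CalibrationResult(
        params=arrays_to_params(a, c),
        loglik=loglik,
        n_iter=it,
        converged=converged,
        grid=grid,
        loglik_path=np.asarray(path),
    )


# --- covariance of the item parameters -------------------------------------

def _louis_information(responses: ResponseMatrix, a, c, grid: QuadratureGrid) -> np.ndarray:
    """Observed information of the marginal log-likelihood via Louis' identity.

    Parameters are stacked item-major on the slope--intercept scale:
    (a_1, c_1, a_2, c_2, ...).
    """
    theta = grid.points
    P = prob_matrix(a, c, theta)
    post = posterior_over_grid(responses, (a, c), grid)
    u1, u0 = responses.indicator_arrays()
    U = u1
    M = u1 + u0
    n = responses.n

    # score vectors per person: s_c = m (u - E_post P), s_a = m (u tbar - E_post theta P)
    A1 = post @ P.T
    A1t = (post * theta) @ P.T
    tbar = post @ theta
    s_c = M * (U - A1)
    s_a = M * (U * tbar[:, None] - A1t)
    S = np.empty((responses.N, 2 * n))
    S[:, 0::2] = s_a
    S[:, 1::2] = s_c
    T3 = S.T @ S

    # E_post[g g'] summed over persons, by powers of theta
    M0 = np.zeros((n, n))
    M1 = np.zeros((n, n))
    M2 = np.zeros((n, n))
    for q in range(grid.Q):
        D = M * (U - P[:, q])
        C = D.T * post[:, q] @ D
        M0 += C
        M1 += theta[q] * C
        M2 += theta[q] ** 2 * C
    A = np.empty((2 * n, 2 * n))
    A[0::2, 0::2] = M2
    A[0::2, 1::2] = M1
    A[1::2, 0::2] = M1
    A[1::2, 1::2] = M0

    # E_post of the (block-diagonal) complete-data Hessian
    w = M.T @ post
    v = w * P * (1.0 - P)
    info = T3 - A
    info[0::2, 0::2][np.diag_indices(n)] += v @ theta**2
    off = v @ theta
    info[0::2, 1::2][np.diag_indices(n)] += off
    info[1::2, 0::2][np.diag_indices(n)] += off
    info[1::2, 1::2][np.diag_indices(n)] += v.sum(axis=1)
    return info


def _numerical_information(responses, a, c, grid, h=1e-4) -> np.ndarray:
    """Central-difference Hessian of the negative marginal log-likelihood."""
    x0 = np.empty(2 * a.size)
    x0[0::2], x0[1::2] = a, c

    def f(x):
        return marginal_loglik(responses, (x[0::2], x[1::2]), grid)

    p = x0.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return -H


def _opg_information(responses, a, c, grid) -> np.ndarray:
    """Outer product of per-person score vectors (empirical Fisher information)."""
    theta = grid.points
    P = prob_matrix(a, c, theta)
    post = posterior_over_grid(responses, (a, c), grid)
    u1, u0 = responses.indicator_arrays()
    M = u1 + u0
    A1 = post @ P.T
    A1t = (post * theta) @ P.T
    tbar = post @ theta
    S = np.empty((responses.N, 2 * a.size))
    S[:, 0::2] = M * (u1 * tbar[:, None] - A1t)
    S[:, 1::2] = M * (u1 - A1)
    return S.T @ S


def param_covariance(
    responses: ResponseMatrix,
    result: CalibrationResult,
    method: str = "louis",
) -> np.ndarray:
    """Covariance matrix of the item-parameter estimates (2n x 2n).

    Ordered item-major on the slope--intercept scale: (a_1, c_1, a_2, c_2,
    ...), the scale on which posterior draws are taken.  ``method`` is one of
    ``"louis"`` (analytic observed information, default), ``"numerical"``
    (central-difference Hessian; small problems only) or ``"opg"`` (outer
    product of gradients).  A non-positive-definite information matrix is
    repaired with the smallest diagonal ridge that makes it so (logged).
    """
    a, c = params_to_arrays(result.params)
    if method == "louis":
        info = _louis_information(responses, a, c, result.grid)
    elif method == "numerical":
        info = _numerical_information(responses, a, c, result.grid)
    elif method == "opg":
        info = _opg_information(responses, a, c, result.grid)
    else:
        raise ValueError(f"unknown covariance method {method!r}")
    info = 0.5 * (info + info.T)
    eigmin = np.linalg.eigvalsh(info)[0]
    if eigmin <= 0:
        ridge = abs(eigmin) + 1e-8 * max(1.0, np.abs(np.diag(info)).max())
        logger.info("information matrix not PD; adding ridge %.3e", ridge)
        info = info + ridge * np.eye(info.shape[0])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise RuntimeError("information matrix is singular") from exc
    return 0.5 * (cov + cov.T)
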