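"""Posterior-predictive significance testing of the per-item RMSD (PP-PPMC).

The parameter posterior is approximated by a multivariate normal centered at
the ML estimates with their sampling covariance ("poor person's" posterior
predictive model checking).  For each of ``L`` draws ``w_l`` from that
approximation, the realized discrepancy ``T(Y_obs, w_l)`` and the predictive
discrepancy ``T(Y_rep_l, w_l)`` are computed, where ``Y_rep_l`` is a fresh
dataset simulated under ``w_l`` with the observed missingness pattern and
``T`` is the per-item RMSD.  The posterior predictive p-value of an item is
the proportion of draws in which the predictive discrepancy strictly exceeds
the realized one; values near 0.5 indicate good fit and small values misfit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationResult, param_covariance
from .data import MISSING, ResponseMatrix
from .model import QuadratureGrid, params_to_arrays
from .rmsd import item_fit

__all__ = [
    "PosteriorApprox",
    "PPMCResult",
    "posterior_approx",
    "draw_parameters",
    "simulate_responses",
    "ppp_values",
    "flag_items",
]

logger = logging.getLogger(__name__)

MIN_SLOPE = 0.05  # draws with any slope at or below this are rejected


@dataclass
class PosteriorApprox:
    """MVN approximation to the item-parameter posterior.

    ``mean`` stacks the parameters item-major on the slope--intercept scale,
    (a_1, c_1, ..., a_n, c_n); ``cov`` is the matching 2n x 2n covariance.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("cov shape does not match mean length")


def posterior_approx(
    responses: ResponseMatrix, result: CalibrationResult, method: str = "louis"
) -> PosteriorApprox:
    """Build the MVN posterior approximation from a calibration result."""
    a, c = params_to_arrays(result.params)
    mean = np.empty(2 * a.size)
    mean[0::2], mean[1::2] = a, c
    return PosteriorApprox(mean=mean, cov=param_covariance(responses, result, method=method))


def draw_parameters(post: PosteriorApprox, L: int, seed) -> np.ndarray:
    """Draw ``L`` parameter vectors from the MVN posterior approximation.

    Any draw containing a slope <= 0.05 is rejected and redrawn, keeping the
    implied 2PL curves increasing; the rejection count is logged and a
    warning is emitted if more than half of all draws are rejected.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chol = np.linalg.cholesky(post.cov)
    draws = np.empty((L, post.mean.size))
    n_rejected = 0
    filled = 0
    while filled < L:
        batch = post.mean + rng.standard_normal((L - filled, post.mean.size)) @ chol.T
        ok = (batch[:, 0::2] > MIN_SLOPE).all(axis=1)
        n_rejected += int((~ok).sum())
        good = batch[ok]
        draws[filled : filled + good.shape[0]] = good
        filled += good.shape[0]
        if n_rejected > 50 * L:  # pragma: no cover - diffuse-posterior safety valve
            raise RuntimeError("posterior too diffuse: rejection rate above 98%")
    if n_rejected > 0:
        logger.info("rejected %d draws with near-zero slopes", n_rejected)
    if n_rejected > 0.5 * (L + n_rejected):
        bad = np.flatnonzero(post.mean[0::2] - 2 * np.sqrt(np.diag(post.cov)[0::2]) <= MIN_SLOPE)
        import warnings

        warnings.warn(
            f"over half of posterior draws rejected; diffuse slopes for items {bad.tolist()}",
            RuntimeWarning,
        )
    return draws


def simulate_responses(params, N: int, seed, missing_mask=None) -> ResponseMatrix:
    """Simulate 2PL responses for ``N`` persons with standard-normal abilities.

    ``params`` is a list of :class:`~irtfit.model.ItemParams2PL` or an
    ``(a, c)`` pair.  If ``missing_mask`` (boolean N x n, True = observed) is
    given, entries outside the mask are set missing, mirroring the observed
    design in replicated data.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a, c = params_to_arrays(params)
    theta = rng.standard_normal(N)
    p = 1.0 / (1.0 + np.exp(-(np.outer(theta, a) + c)))
    data = (rng.random((N, a.size)) < p).astype(np.int8)
    if missing_mask is not None:
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if missing_mask.shape != data.shape:
            raise ValueError("missing_mask shape does not match (N, n)")
        data[~missing_mask] = MISSING
    return ResponseMatrix(data)


@dataclass
class PPMCResult:
    """Realized and predictive RMSD draws with per-item PPP values."""

    realized: np.ndarray  # item x L
    predictive: np.ndarray  # item x L
    ppp: np.ndarray
    L: int
    n_redrawn: int = 0


def ppp_values(
    responses: ResponseMatrix,
    calres: CalibrationResult,
    post: PosteriorApprox,
    L: int = 100,
    seed=None,
) -> PPMCResult:
    """Compute per-item posterior predictive p-values for the RMSD.

    For each draw the observed data's pseudocounts and the expected curves
    are both evaluated at the drawn parameters, and the replicate inherits
    the observed missingness mask.  Ties between predictive and realized
    discrepancies count as non-exceedance (strict inequality).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = calres.grid
    draws = draw_parameters(post, L, rng)
    mask = responses.mask
    n = responses.n
    realized = np.empty((n, L))
    predictive = np.empty((n, L))
    n_redrawn = 0
    for l in range(L):
        params_l = (draws[l, 0::2], draws[l, 1::2])
        for attempt in range(10):
            try:
                realized[:, l] = item_fit(responses, params_l, grid).rmsd
                rep = simulate_responses(params_l, responses.N, rng, missing_mask=mask)
                predictive[:, l] = item_fit(rep, params_l, grid).rmsd
                break
            except (ValueError, FloatingPointError):  # degenerate replicate; redraw
                n_redrawn += 1
                logger.info("redrawing failed draw %d (attempt %d)", l, attempt + 1)
                params_l_vec = draw_parameters(post, 1, rng)[0]
                params_l = (params_l_vec[0::2], params_l_vec[1::2])
        else:  # pragma: no cover - persistent failure
            raise RuntimeError(f"draw {l} failed after 10 redraws")
    ppp = (predictive > realized).mean(axis=1)
    return PPMCResult(realized=realized, predictive=predictive, ppp=ppp, L=L, n_redrawn=n_redrawn)


def flag_items(result: PPMCResult, alpha: float = 0.05) -> np.ndarray:
    """Flag items whose PPP value falls strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return result.ppp < alpha
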