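"""Item response functions, quadrature, and population-density weights.

The two-parameter logistic (2PL) model gives the probability of a correct
response as ``P(theta) = 1 / (1 + exp(-a (theta - b)))`` with slope
(discrimination) ``a > 0`` and difficulty ``b``.  Internally the
slope--intercept form ``logit P = a*theta + c`` with ``c = -a*b`` is used for
estimation stability; the slope--difficulty form is the user-facing
convention.

Misfitting items are described by a logistic function of a monotonic
polynomial with a lower asymptote (LMPA),

    P(theta) = g + (1 - g) / (1 + exp(-(delta + f(theta)))),

where ``f`` is an odd-order polynomial of order ``2k + 1`` whose derivative

    f'(theta) = exp(omega) * prod_s (1 - 2 a_s theta + (a_s^2 + exp(t_s)) theta^2)

is strictly positive (each quadratic factor has discriminant ``-4 exp(t_s)``),
so the item response function is monotone for any parameter values.  For
``k = 0`` the model reduces to the 3PL with slope ``exp(omega)``, intercept
``delta`` and guessing parameter ``g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "QuadratureGrid",
    "ItemParams2PL",
    "LMPAParams",
    "make_grid",
    "icc_2pl",
    "mono_poly_coeffs",
    "irf_lmpa",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced latent-trait points with normalized N(0,1) density weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least 2 points")
        if w.shape != pts.shape:
            raise ValueError("points and weights must have equal length")
        d = np.diff(pts)
        if not np.all(d > 0) or not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("points must be strictly increasing and equally spaced")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def Q(self) -> int:
        return self.points.size


def make_grid(Q: int = 81, lo: float = -4.0, hi: float = 4.0) -> QuadratureGrid:
    """Build a quadrature grid of ``Q`` equally spaced points on ``[lo, hi]``.

    Weights are the standard-normal density at each point normalized to sum
    to one.  The default (81 points on [-4, 4], spacing 0.1) is the grid used
    for both calibration and item-fit analysis throughout the package.
    """
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError("grid bounds must be finite with lo < hi")
    Q = int(Q)
    if Q < 2:
        raise ValueError("Q must be at least 2")
    points = np.linspace(lo, hi, Q)
    dens = norm.pdf(points)
    return QuadratureGrid(points=points, weights=dens / dens.sum())


@dataclass(frozen=True)
class ItemParams2PL:
    """2PL item parameters in slope--difficulty form.

    The intercept ``c = -a * b`` of the slope--intercept form is derived.
    """

    slope: float
    difficulty: float

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not np.isfinite(self.difficulty):
            raise ValueError("difficulty must be finite")

    @property
    def intercept(self) -> float:
        return -self.slope * self.difficulty


def params_to_arrays(params) -> tuple[np.ndarray, np.ndarray]:
    """Stack item parameters into (slope, intercept) arrays.

    Accepts a sequence of :class:`ItemParams2PL` or a pair of arrays
    ``(a, c)`` already in slope--intercept form.
    """
    if isinstance(params, tuple) and len(params) == 2:
        a = np.asarray(params[0], dtype=float)
        c = np.asarray(params[1], dtype=float)
        return a, c
    a = np.array([p.slope for p in params], dtype=float)
    c = np.array([p.intercept for p in params], dtype=float)
    return a, c


def arrays_to_params(a: np.ndarray, c: np.ndarray) -> list[ItemParams2PL]:
    return [ItemParams2PL(slope=ai, difficulty=-ci / ai) for ai, ci in zip(a, c)]


def icc_2pl(params, theta):
    """2PL item characteristic curve ``1 / (1 + exp(-a (theta - b)))``.

    ``params`` may be an :class:`ItemParams2PL` or an ``(a, b)`` pair of
    scalars.  ``theta`` may be a scalar or an array; the return matches its
    shape.
    """
    if isinstance(params, ItemParams2PL):
        a, b = params.slope, params.difficulty
    else:
        a, b = params
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    out = expit(a * (theta - b))
    return float(out) if out.ndim == 0 else out


def prob_matrix(a: np.ndarray, c: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Item x quadrature matrix of 2PL probabilities in slope--intercept form."""
    return expit(np.outer(a, points) + np.asarray(c, dtype=float)[:, None])


def mono_poly_coeffs(k: int, omega: float, alpha=(), tau=()) -> np.ndarray:
    """Polynomial coefficients ``b = (b1, ..., b_{2k+1})`` of the LMPA core.

    The derivative of the polynomial is defined as

        f'(theta) = exp(omega) * prod_{s=1..k} (1 - 2 alpha_s theta
                                                + (alpha_s^2 + exp(tau_s)) theta^2)

    which is expanded and integrated term-wise with ``f(0) = 0``.  Each
    quadratic factor has negative discriminant, so ``f`` is strictly
    increasing; for ``k = 0`` the result is the single slope ``exp(omega)``.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float)) if k else np.empty(0)
    tau = np.atleast_1d(np.asarray(tau, dtype=float)) if k else np.empty(0)
    if alpha.size != k or tau.size != k:
        raise ValueError(f"alpha and tau must have length k={k}")
    deriv = np.array([np.exp(omega)])
    for a_s, t_s in zip(alpha, tau):
        deriv = npoly.polymul(deriv, [1.0, -2.0 * a_s, a_s**2 + np.exp(t_s)])
    # integrate with zero constant: coefficient of theta^m is deriv[m-1]/m
    return deriv / np.arange(1, deriv.size + 1)


@dataclass(frozen=True)
class LMPAParams:
    """Parameters of the LMPA item response function.

    ``k`` controls the polynomial order ``2k + 1``; ``g`` is the lower
    asymptote; ``omega`` the log slope; ``delta`` the intercept; ``alpha``
    and ``tau`` (each length ``k``) place and size the plateaus of the curve.
    """

    k: int
    g: float
    omega: float
    delta: float
    alpha: tuple = ()
    tau: tuple = ()
    b_coeffs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be a nonnegative integer")
        if not 0 <= self.g < 1:
            raise ValueError("g must lie in [0, 1)")
        object.__setattr__(self, "alpha", tuple(np.atleast_1d(self.alpha)) if self.k else ())
        object.__setattr__(self, "tau", tuple(np.atleast_1d(self.tau)) if self.k else ())
        if len(self.alpha) != self.k or len(self.tau) != self.k:
            raise ValueError(f"alpha and tau must have length k={self.k}")
        object.__setattr__(
            self, "b_coeffs", mono_poly_coeffs(self.k, self.omega, self.alpha, self.tau)
        )


def lmpa_core(params: LMPAParams, theta):
    """Evaluate the monotone polynomial ``f(theta)`` of an LMPA item."""
    theta = np.asarray(theta, dtype=float)
    # b_coeffs are for powers 1..2k+1; prepend the zero constant term
    return npoly.polyval(theta, np.concatenate(([0.0], params.b_coeffs)))


def irf_lmpa(params: LMPAParams, theta):
    """LMPA item response function ``g + (1-g) * sigmoid(delta + f(theta))``."""
    theta = np.asarray(theta, dtype=float)
    out = params.g + (1.0 - params.g) * expit(params.delta + lmpa_core(params, theta))
    return float(out) if out.ndim == 0 else out
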