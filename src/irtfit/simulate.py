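"""Data-generating process for the calibration studies.

Fitting items follow the 2PL with slopes from a truncated lognormal (log
mean 0, log variance 0.5, truncated by redraw to [0.25, 4.00] -- the 2.5th
and 97.5th percentiles) and difficulties from N(0,1) truncated to
[-1.96, 1.96].  Misfitting items are drawn from a pre-built pool of LMPA
parameter combinations whose *population RMSD* -- the density-weighted RMSD
between the true curve and its best 2PL approximation, free of sampling
error -- exceeds a threshold (0.05, medium-to-large misfit).  Abilities are
standard normal; random missingness removes an exact per-person count of
responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data import MISSING, ResponseMatrix
from .model import ItemParams2PL, LMPAParams, QuadratureGrid, irf_lmpa, make_grid

__all__ = [
    "MisfitPool",
    "SimulationCondition",
    "GeneratedDataset",
    "sample_fitting_params",
    "best_2pl_approx",
    "enumerate_lmpa_grid",
    "build_lmpa_pool",
    "generate_dataset",
    "impose_missingness",
]

logger = logging.getLogger(__name__)

SLOPE_SIGMA = np.sqrt(0.5)  # log-scale SD of the lognormal slope distribution
SLOPE_BOUNDS = (0.25, 4.00)
DIFF_BOUNDS = (-1.96, 1.96)
# plausibility box for the best-approximating 2PL: within 2 SD of the
# generating distributions (log-scale for the slope)
LOG_SLOPE_BOX = 2.0 * SLOPE_SIGMA
DIFF_BOX = 2.0


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_fitting_params(count: int, seed) -> list[ItemParams2PL]:
    """Sample 2PL parameters for fitting items (truncation by redraw)."""
    if count < 1:
        raise ValueError("count must be at least 1")
    rng = _as_rng(seed)

    def trunc(draw, lo, hi, size):
        out = draw(size)
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = draw(int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out

    slopes = trunc(lambda s: rng.lognormal(0.0, SLOPE_SIGMA, s), *SLOPE_BOUNDS, count)
    diffs = trunc(lambda s: rng.normal(0.0, 1.0, s), *DIFF_BOUNDS, count)
    return [ItemParams2PL(slope=a, difficulty=b) for a, b in zip(slopes, diffs)]


# --- best 2PL approximation to an arbitrary curve ---------------------------

_START_GRID = [(0.5, 0.0), (1.0, 0.0), (2.0, 0.0), (1.0, -1.0), (1.0, 1.0), (0.7, 1.5), (0.7, -1.5)]


def _batch_best_2pl(curves: np.ndarray, grid: QuadratureGrid, extra_starts=()):
    """Weighted least-squares 2PL fit to each row of ``curves``.

    Damped Gauss--Newton from several starting values, vectorized across
    curves; returns (a, b, rmsd) arrays where rmsd is the square root of the
    minimized density-weighted objective.
    """
    T = np.atleast_2d(np.asarray(curves, dtype=float))
    theta = grid.points
    w = grid.weights
    best_a = np.full(T.shape[0], np.nan)
    best_b = np.full(T.shape[0], np.nan)
    best_loss = np.full(T.shape[0], np.inf)

    def loss(a, b):
        e = T - expit(a[:, None] * (theta - b[:, None]))
        return (e * e) @ w

    starts = list(_START_GRID) + list(extra_starts)
    # data-driven start: weighted logit regression of the clipped curve
    logit_t = np.log(np.clip(T, 1e-3, 1 - 1e-3) / (1 - np.clip(T, 1e-3, 1 - 1e-3)))
    sw = w / w.sum()
    mt = (logit_t * sw).sum(axis=1)
    mx = (theta * sw).sum()
    a0 = ((logit_t - mt[:, None]) * (theta - mx) * sw).sum(axis=1) / (((theta - mx) ** 2) * sw).sum()
    a0 = np.clip(a0, 0.05, 8.0)
    b0 = np.clip(mx - mt / a0, -4.0, 4.0)
    start_list = [(a0, b0)] + [
        (np.full(T.shape[0], sa), np.full(T.shape[0], sb)) for sa, sb in starts
    ]

    for a, b in start_list:
        a, b = a.copy().astype(float), b.copy().astype(float)
        f = loss(a, b)
        for _ in range(200):
            P = expit(a[:, None] * (theta - b[:, None]))
            r = T - P
            dP = P * (1 - P)
            Ja = dP * (theta - b[:, None])
            Jb = -dP * a[:, None]
            gaa = (Ja * Ja) @ w + 1e-10
            gab = (Ja * Jb) @ w
            gbb = (Jb * Jb) @ w + 1e-10
            ga = (Ja * r) @ w
            gb = (Jb * r) @ w
            det = gaa * gbb - gab * gab
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            da = (gbb * ga - gab * gb) / det
            db = (gaa * gb - gab * ga) / det
            if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < 1e-10:
                break
            step = np.ones_like(a)
            for _ in range(30):
                a_new = np.clip(a + step * da, 1e-3, 50.0)
                b_new = np.clip(b + step * db, -20.0, 20.0)
                f_new = loss(a_new, b_new)
                worse = f_new > f + 1e-15
                if not worse.any():
                    break
                step[worse] *= 0.5
            a, b = a_new, b_new
            moved = f - f_new
            f = f_new
            if moved.max(initial=0.0) < 1e-15:
                break
        better = f < best_loss
        best_a[better], best_b[better], best_loss[better] = a[better], b[better], f[better]
    return best_a, best_b, np.sqrt(best_loss)


def best_2pl_approx(true_curve, grid: QuadratureGrid, extra_starts=()):
    """Best density-weighted 2PL approximation to a true IRF on the grid.

    Returns ``(ItemParams2PL, population_rmsd)`` where the population RMSD
    is the square root of the minimized weighted squared deviation.
    """
    curve = np.asarray(true_curve, dtype=float)
    if curve.ndim != 1 or curve.shape != grid.points.shape:
        raise ValueError("curve must be a vector over the grid points")
    if np.any((curve < 0) | (curve > 1)):
        raise ValueError("curve values must lie in [0, 1]")
    a, b, r = _batch_best_2pl(curve[None, :], grid, extra_starts)
    if not np.isfinite(a[0]):  # pragma: no cover
        raise RuntimeError("2PL approximation failed from all starting values")
    return ItemParams2PL(slope=float(a[0]), difficulty=float(b[0])), float(r[0])


# --- LMPA pool ---------------------------------------------------------------

def enumerate_lmpa_grid(k: int) -> list[LMPAParams]:
    """Enumerate the preliminary-analysis LMPA parameter grid for order k.

    k=0: g in {0.1, 0.2, 0.3} x omega at the nine N(0,1) deciles x delta in
    -1.6..1.6 by 0.4 (243 combinations).  k=1 additionally allows g=0 and
    crosses alpha in -0.99..0.99 by 0.22 with exp(tau) in 0.01..1.21 by 0.2
    (22,680 combinations).
    """
    omegas = norm.ppf(np.arange(1, 10) / 10.0)
    deltas = np.arange(-1.6, 1.6 + 1e-9, 0.4)
    out = []
    if k == 0:
        for g in (0.1, 0.2, 0.3):
            for om in omegas:
                for d in deltas:
                    out.append(LMPAParams(k=0, g=g, omega=om, delta=d))
    elif k == 1:
        alphas = np.arange(-0.99, 0.99 + 1e-9, 0.22)
        exp_taus = np.arange(0.01, 1.21 + 1e-9, 0.2)
        for g in (0.0, 0.1, 0.2, 0.3):
            for om in omegas:
                for d in deltas:
                    for al in alphas:
                        for et in exp_taus:
                            out.append(
                                LMPAParams(k=1, g=g, omega=om, delta=d,
                                           alpha=(al,), tau=(np.log(et),))
                            )
    else:
        raise ValueError("only k in {0, 1} is enumerated")
    return out


@dataclass
class MisfitPool:
    """LMPA combinations producing medium-to-large population misfit."""

    params: list[LMPAParams]
    best2pl: list[ItemParams2PL]
    population_rmsd: np.ndarray
    threshold: float
    enumerated: dict = field(default_factory=dict)  # combos examined per k

    def __len__(self) -> int:
        return len(self.params)

    def sample(self, count: int, rng) -> list[int]:
        return list(_as_rng(rng).integers(0, len(self.params), size=count))


def build_lmpa_pool(grid: QuadratureGrid | None = None, threshold: float = 0.05,
                    ks=(0, 1)) -> MisfitPool:
    """Build the misfit pool by filtering the enumerated LMPA grids.

    For every combination the best density-weighted 2PL approximation is
    computed; combinations whose fitted slope leaves the 2-SD log-scale box
    or whose fitted difficulty leaves [-2, 2] are excluded as implausible,
    and of the rest only those with population RMSD above ``threshold`` are
    retained.  Deterministic: no randomness is involved.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    grid = grid if grid is not None else make_grid()
    combos: list[LMPAParams] = []
    enumerated = {}
    for k in ks:
        batch = enumerate_lmpa_grid(k)
        enumerated[k] = len(batch)
        combos.extend(batch)
    curves = np.vstack([irf_lmpa(p, grid.points) for p in combos])
    a, b, rms = _batch_best_2pl(curves, grid)
    keep = (
        (np.abs(np.log(a)) <= LOG_SLOPE_BOX)
        & (np.abs(b) <= DIFF_BOX)
        & (rms > threshold)
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("misfit pool is empty under the given threshold")
    logger.info("LMPA pool: %d of %d combinations retained", idx.size, len(combos))
    return MisfitPool(
        params=[combos[i] for i in idx],
        best2pl=[ItemParams2PL(slope=a[i], difficulty=b[i]) for i in idx],
        population_rmsd=rms[idx],
        threshold=threshold,
        enumerated=enumerated,
    )


# --- dataset generation ------------------------------------------------------

@dataclass
class SimulationCondition:
    """A study condition: sample size, test length, misfit and missing rates."""

    N: int
    n: int
    prop_misfit: float = 0.0
    prop_missing: float = 0.0
    reps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.N < 1 or self.n < 1 or self.reps < 1:
            raise ValueError("N, n and reps must be at least 1")
        if not (0 <= self.prop_misfit < 1 and 0 <= self.prop_missing < 1):
            raise ValueError("proportions must lie in [0, 1)")


@dataclass
class GeneratedDataset:
    """Simulated responses with the generating truth attached."""

    responses: ResponseMatrix
    abilities: np.ndarray
    item_params: list  # per-item ItemParams2PL or LMPAParams
    is_misfit: np.ndarray
    population_rmsd: np.ndarray  # NaN for fitting items


def generate_dataset(cond: SimulationCondition, pool: MisfitPool | None = None, seed=None) -> GeneratedDataset:
    """Generate one dataset under a study condition.

    ``round(prop_misfit * n)`` items (ties to even) are drawn uniformly from
    the pool and placed at random positions; the rest are fitting items.
    Abilities are standard normal; responses Bernoulli from each item's true
    curve; missingness, if any, is imposed last.
    """
    rng = _as_rng(seed if seed is not None else cond.seed)
    n_misfit = int(np.rint(cond.prop_misfit * cond.n))
    if n_misfit > 0 and (pool is None or len(pool) == 0):
        raise ValueError("a nonempty misfit pool is required when prop_misfit > 0")
    misfit_pos = set(rng.choice(cond.n, size=n_misfit, replace=False).tolist()) if n_misfit else set()
    fitting = sample_fitting_params(max(cond.n - n_misfit, 1), rng)[: cond.n - n_misfit]
    pool_idx = pool.sample(n_misfit, rng) if n_misfit else []

    theta = rng.standard_normal(cond.N)
    item_params, is_misfit, pop_rmsd = [], np.zeros(cond.n, dtype=bool), np.full(cond.n, np.nan)
    probs = np.empty((cond.N, cond.n))
    fit_iter, mis_iter = iter(fitting), iter(pool_idx)
    for i in range(cond.n):
        if i in misfit_pos:
            j = next(mis_iter)
            p = pool.params[j]
            probs[:, i] = irf_lmpa(p, theta)
            is_misfit[i] = True
            pop_rmsd[i] = pool.population_rmsd[j]
        else:
            p = next(fit_iter)
            probs[:, i] = expit(p.slope * (theta - p.difficulty))
        item_params.append(p)
    data = (rng.random((cond.N, cond.n)) < probs).astype(np.int8)
    responses = ResponseMatrix(data)
    if cond.prop_missing > 0:
        responses = impose_missingness(responses, cond.prop_missing, rng)
    return GeneratedDataset(
        responses=responses,
        abilities=theta,
        item_params=item_params,
        is_misfit=is_misfit,
        population_rmsd=pop_rmsd,
    )


def impose_missingness(responses: ResponseMatrix, prop: float, seed) -> ResponseMatrix:
    """Set exactly ``round(prop * n)`` responses per person to missing.

    The removed items are chosen uniformly without replacement,
    independently per person.  If some item would lose all of its correct or
    incorrect valid responses the pattern is regenerated (up to 10 attempts,
    logged) before giving up.
    """
    if not 0 <= prop < 1:
        raise ValueError("prop must lie in [0, 1)")
    if prop == 0:
        return responses
    rng = _as_rng(seed)
    n_miss = int(np.rint(prop * responses.n))
    if n_miss >= responses.n:
        raise ValueError("cannot remove every response of a person")
    if n_miss == 0:
        return responses
    for attempt in range(10):
        order = np.argsort(rng.random((responses.N, responses.n)), axis=1)
        drop = order[:, :n_miss]
        data = responses.data.copy()
        np.put_along_axis(data, drop, MISSING, axis=1)
        nc = (data == 1).sum(axis=0)
        nv = (data != MISSING).sum(axis=0)
        if np.all((nc >= 1) & (nv - nc >= 1)):
            return responses.with_data(data)
        logger.info("missingness attempt %d left a degenerate item; regenerating", attempt + 1)
    raise RuntimeError("could not impose missingness without degenerating an item")
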