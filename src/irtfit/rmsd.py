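"""Pseudocount aggregation and the density-weighted RMSD item-fit statistic.

Each person's normalized posterior over the quadrature points (the *unit
pseudocounts*) is accumulated per item into expected counts for the correct
and incorrect categories.  Dividing the correct-category pseudocounts by the
total gives an observed item response function on the quadrature grid, which
is compared with the model-implied curve.  The RMSD of item ``i`` is

    RMSD_i = sqrt( sum_q w_q (p_iq - Pi_iq)^2 )

with ``w_q`` the normalized standard-normal density weights, ``p_iq`` the
observed and ``Pi_iq`` the expected probability at quadrature point ``q``.
A guard constant of 0.001 is added to the denominator of ``p_iq`` only where
the total pseudocount mass is essentially zero (below 1e-10), defining
``p_iq = 0`` at quadrature points no respondent occupies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import posterior_over_grid
from .data import ResponseMatrix
from .model import QuadratureGrid, params_to_arrays, prob_matrix

__all__ = [
    "PseudocountTable",
    "ItemFitResult",
    "aggregate_pseudocounts",
    "observed_probs",
    "expected_probs",
    "rmsd",
    "item_fit",
]

GUARD = 0.001
GUARD_THRESHOLD = 1e-10


@dataclass
class PseudocountTable:
    """Per-item, per-quadrature pseudocount accumulations (the E-table)."""

    s1: np.ndarray  # item x quadrature, correct category
    s0: np.ndarray  # item x quadrature, incorrect category
    n_valid: np.ndarray
    n_correct: np.ndarray


def aggregate_pseudocounts(responses: ResponseMatrix, params, grid: QuadratureGrid) -> PseudocountTable:
    """Accumulate unit pseudocounts into per-item category counts.

    Persons missing item ``i`` contribute to neither category of that item,
    so each item's pseudocounts conserve exactly its valid-response counts:
    ``sum_q s1_iq = N_i1`` and ``sum_q (s1_iq + s0_iq) = N_i``.
    """
    if np.any(responses.n_valid == 0):
        bad = [responses.item_ids[i] for i in np.flatnonzero(responses.n_valid == 0)]
        raise ValueError(f"items without any valid response: {bad}")
    post = posterior_over_grid(responses, params, grid)
    u1, u0 = responses.indicator_arrays()
    return PseudocountTable(
        s1=u1.T @ post,
        s0=u0.T @ post,
        n_valid=responses.n_valid,
        n_correct=responses.n_correct,
    )


def observed_probs(table: PseudocountTable) -> np.ndarray:
    """Observed probabilities ``p_iq`` from a pseudocount table."""
    denom = table.s1 + table.s0
    return table.s1 / (denom + GUARD * (denom < GUARD_THRESHOLD))


def expected_probs(params, grid: QuadratureGrid) -> np.ndarray:
    """Model-implied probabilities ``Pi_iq`` (the 2PL tracelines on the grid)."""
    a, c = params_to_arrays(params)
    return prob_matrix(a, c, grid.points)


def rmsd(observed_row, expected_row, weights) -> float:
    """Density-weighted root mean squared deviation of one item."""
    p = np.asarray(observed_row, dtype=float)
    pi = np.asarray(expected_row, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (p.shape == pi.shape == w.shape):
        raise ValueError("observed, expected and weights must have equal length")
    e = p - pi
    return float(np.sqrt(w @ (e * e)))


@dataclass
class ItemFitResult:
    """Observed/expected curves, deviations and per-item RMSD."""

    item_ids: list
    observed: np.ndarray
    expected: np.ndarray
    weights: np.ndarray
    rmsd: np.ndarray
    n_valid: np.ndarray
    n_correct: np.ndarray

    @property
    def deviations(self) -> np.ndarray:
        return self.observed - self.expected

    def to_frame(self) -> pd.DataFrame:
        """Item-fit report as a tidy per-item table."""
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "n_valid": self.n_valid,
                "n_correct": self.n_correct,
                "rmsd": self.rmsd,
            }
        )

    def curves_frame(self, grid: QuadratureGrid) -> pd.DataFrame:
        """Tidy table of observed/expected curves for plotting."""
        n, Q = self.observed.shape
        return pd.DataFrame(
            {
                "item_id": np.repeat(self.item_ids, Q),
                "quadrature": np.tile(grid.points, n),
                "observed": self.observed.ravel(),
                "expected": self.expected.ravel(),
                "weight": np.tile(self.weights, n),
            }
        )


def item_fit(
    responses: ResponseMatrix,
    params,
    grid: QuadratureGrid,
    weights=None,
) -> ItemFitResult:
    """Full per-item RMSD analysis under the supplied 2PL parameters.

    ``params`` is typically the calibrated MLE; for posterior-predictive
    checks the same routine is evaluated at each posterior draw.  ``weights``
    defaults to the grid's density weights but accepts any nonnegative vector
    summing to one (e.g., a uniform weighting).
    """
    w = grid.weights if weights is None else np.asarray(weights, dtype=float)
    table = aggregate_pseudocounts(responses, params, grid)
    obs = observed_probs(table)
    exp = expected_probs(params, grid)
    dev = obs - exp
    return ItemFitResult(
        item_ids=list(responses.item_ids),
        observed=obs,
        expected=exp,
        weights=w,
        rmsd=np.sqrt((dev * dev) @ w),
        n_valid=table.n_valid,
        n_correct=table.n_correct,
    )
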