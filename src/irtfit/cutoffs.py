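"""ROC-derived reference values for the RMSD and their response-surface model.

Given RMSD samples from correctly specified (null) and misspecified (alt)
items, every candidate threshold on a fine grid (default step 0.001) is
scored by sensitivity (flagged fraction of misfitting items; an item is
flagged when its RMSD is at or above the threshold) and specificity
(unflagged fraction of fitting items).  The recommended reference value is
the lower bound of the threshold interval maximizing Youden's
J = Se + Sp - 1; taking the lower bound guards against the loss of
sensitivity caused by missing data, which shrinks misfitting items' RMSD
while leaving fitting items' RMSD stable.

Reference values depend strongly on sample size N and test length n, so a
polynomial response-surface regression of optimized cutoffs on
(sqrt(n), sqrt(N), n, N, n^{3/2}, N^{3/2}) interpolates them to unstudied
(N, n).  The default coefficients were estimated from large simulation
studies spanning N in [500, 50,000] and n in [20, 400] and are shipped as
data; :func:`fit_surface_model` refits the same model families to new
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm

__all__ = [
    "ROCResult",
    "CutoffRecommendation",
    "SurfaceModel",
    "roc_curve",
    "youden_optimal",
    "apply_cutoff",
    "fit_surface_model",
    "select_surface_model",
    "predict_reference_value",
    "DEFAULT_SURFACE_MODEL",
]

_EPS = 1e-12


@dataclass
class ROCResult:
    """Sensitivity/specificity sweep over a threshold grid."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_curve(null_rmsd, alt_rmsd, step: float = 0.001) -> ROCResult:
    """Construct the ROC over an arithmetic threshold grid.

    The grid spans the pooled observed range with spacing ``step``.  An item
    is flagged when its RMSD is at or above the threshold (up to a 1e-12
    float tolerance).
    """
    null_rmsd = np.sort(np.asarray(null_rmsd, dtype=float))
    alt_rmsd = np.sort(np.asarray(alt_rmsd, dtype=float))
    if null_rmsd.size == 0 or alt_rmsd.size == 0:
        raise ValueError("null and alt RMSD samples must be nonempty")
    if step <= 0:
        raise ValueError("step must be positive")
    lo = min(null_rmsd[0], alt_rmsd[0])
    hi = max(null_rmsd[-1], alt_rmsd[-1])
    k0 = int(np.floor(lo / step))
    k1 = int(np.ceil(hi / step))
    thr = np.arange(k0, k1 + 1) * step
    # flagged iff value >= threshold - eps
    se = 1.0 - np.searchsorted(alt_rmsd, thr - _EPS, side="left") / alt_rmsd.size
    sp = np.searchsorted(null_rmsd, thr - _EPS, side="left") / null_rmsd.size
    return ROCResult(thresholds=thr, sensitivity=se, specificity=sp)


@dataclass
class CutoffRecommendation:
    """Youden-optimal threshold interval; the lower bound is recommended."""

    optimal_interval: tuple
    recommended: float
    max_j: float
    fp_rate: float
    tp_rate: float
    contiguous: bool = True


def youden_optimal(roc: ROCResult) -> CutoffRecommendation:
    """Thresholds attaining the maximum of Youden's J.

    When several thresholds tie, the contiguous run containing the lowest
    one is reported as the optimal interval and its lower bound recommended
    (favoring sensitivity); disjoint tying regions are signalled via
    ``contiguous=False``.
    """
    j = roc.youden
    jmax = j.max()
    at_max = np.flatnonzero(j >= jmax - _EPS)
    breaks = np.flatnonzero(np.diff(at_max) > 1)
    first_run_end = at_max[breaks[0]] if breaks.size else at_max[-1]
    lo_idx = at_max[0]
    interval = (float(roc.thresholds[lo_idx]), float(roc.thresholds[first_run_end]))
    return CutoffRecommendation(
        optimal_interval=interval,
        recommended=interval[0],
        max_j=float(jmax),
        fp_rate=float(1.0 - roc.specificity[lo_idx]),
        tp_rate=float(roc.sensitivity[lo_idx]),
        contiguous=breaks.size == 0,
    )


class Rates(NamedTuple):
    fp_rate: float
    tp_rate: float


def apply_cutoff(rmsd_values, labels, cutoff: float) -> Rates:
    """False- and true-positive rates of flagging RMSD >= cutoff against truth."""
    v = np.asarray(rmsd_values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape:
        raise ValueError("rmsd_values and labels must have equal length")
    flags = v >= cutoff - _EPS
    fp = float(flags[~lab].mean()) if (~lab).any() else 0.0
    tp = float(flags[lab].mean()) if lab.any() else 0.0
    return Rates(fp_rate=fp, tp_rate=tp)


# --- response-surface models -------------------------------------------------

PREDICTOR_SETS: dict[int, tuple[str, ...]] = {
    1: ("sqrt_n", "sqrt_N"),
    2: ("sqrt_n", "sqrt_N", "n", "N"),
    3: ("sqrt_n", "sqrt_N", "n", "N", "sqrt_n*sqrt_N"),
    4: ("sqrt_n", "sqrt_N", "n", "N", "n^1.5", "N^1.5"),
    5: ("sqrt_n", "sqrt_N", "n", "N", "n^1.5", "N^1.5", "sqrt_n*N"),
    6: ("sqrt_n", "sqrt_N", "n", "N", "n^1.5", "N^1.5", "n*sqrt_N"),
    7: ("sqrt_n", "sqrt_N", "n", "N", "n^1.5", "N^1.5", "n*N"),
}

_PREDICTOR_FUNCS = {
    "sqrt_n": lambda N, n: np.sqrt(n),
    "sqrt_N": lambda N, n: np.sqrt(N),
    "n": lambda N, n: n,
    "N": lambda N, n: N,
    "n^1.5": lambda N, n: n**1.5,
    "N^1.5": lambda N, n: N**1.5,
    "sqrt_n*sqrt_N": lambda N, n: np.sqrt(n) * np.sqrt(N),
    "sqrt_n*N": lambda N, n: np.sqrt(n) * N,
    "n*sqrt_N": lambda N, n: n * np.sqrt(N),
    "n*N": lambda N, n: n * N,
}


@dataclass
class SurfaceModel:
    """Polynomial regression of optimized cutoffs on sample size and test length."""

    model_id: int
    coefficients: dict  # "intercept" plus predictor names
    r2: float | None = None
    adj_r2: float | None = None

    def predict(self, N, n) -> float:
        z = self.coefficients["intercept"]
        for name, beta in self.coefficients.items():
            if name != "intercept":
                z = z + beta * _PREDICTOR_FUNCS[name](np.asarray(N, float), np.asarray(n, float))
        return z

    def save(self, path) -> None:
        """Write model id and named coefficients (full precision) as JSON."""
        import json

        with open(path, "w") as fh:
            json.dump(
                {"model_id": self.model_id, "coefficients": self.coefficients,
                 "r2": self.r2, "adj_r2": self.adj_r2},
                fh, indent=2,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SurfaceModel":
        import json

        with open(path) as fh:
            raw = json.load(fh)
        return cls(model_id=raw["model_id"], coefficients=raw["coefficients"],
                   r2=raw.get("r2"), adj_r2=raw.get("adj_r2"))


# Published coefficients of the selected model (Model 4), estimated from the
# Youden-optimal cutoffs of the calibration studies.
DEFAULT_SURFACE_MODEL = SurfaceModel(
    model_id=4,
    coefficients={
        "intercept": -0.0025542254,
        "sqrt_n": 0.0128772104,
        "sqrt_N": -0.0006866889,
        "n": -0.0008641079,
        "N": 0.0000044058,
        "n^1.5": 0.0000202367,
        "N^1.5": -0.0000000099,
    },
    adj_r2=0.942,
)


def _design(points, names) -> tuple[np.ndarray, np.ndarray]:
    pts = [(float(N), float(n), float(z)) for N, n, z in points]
    N = np.array([p[0] for p in pts])
    n = np.array([p[1] for p in pts])
    z = np.array([p[2] for p in pts])
    X = np.column_stack([np.ones_like(N)] + [_PREDICTOR_FUNCS[name](N, n) for name in names])
    return X, z


def fit_surface_model(points, model_id: int = 4) -> SurfaceModel:
    """OLS fit of one predictor set to ``(N, n, cutoff)`` points."""
    names = PREDICTOR_SETS[model_id]
    X, z = _design(points, names)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(f"model {model_id} needs at least {X.shape[1] + 1} points")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(z, X).fit()
    coefs = {"intercept": float(fit.params[0])}
    coefs.update({name: float(b) for name, b in zip(names, fit.params[1:])})
    return SurfaceModel(model_id=model_id, coefficients=coefs,
                        r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj))


def select_surface_model(points) -> SurfaceModel:
    """Fit every candidate predictor set and keep the highest adjusted R^2."""
    fits = [fit_surface_model(points, mid) for mid in PREDICTOR_SETS]
    return max(fits, key=lambda m: m.adj_r2)


class PredictedCutoff(NamedTuple):
    value: float  # rounded to the 3-decimal reporting precision
    raw: float


def predict_reference_value(N, n, model: SurfaceModel = DEFAULT_SURFACE_MODEL) -> PredictedCutoff:
    """Reference value tailored to a dataset's sample size and test length."""
    if N < 1 or n < 1:
        raise ValueError("N and n must be at least 1")
    raw = float(model.predict(N, n))
    if raw < 0:
        warnings.warn(
            f"predicted reference value {raw:.4f} is negative (out-of-range "
            "extrapolation); flooring at 0",
            RuntimeWarning,
        )
        raw = 0.0
    return PredictedCutoff(value=round(raw, 3), raw=raw)
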