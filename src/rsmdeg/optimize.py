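"""Exact optimisation of a fitted quadratic surface over a coded box.

A quadratic on a box attains its maximum either at the interior
stationary point or on a face; enumerating all 3^k face configurations
(each coordinate free, at the lower bound, or at the upper bound) and
solving the reduced stationary system on each face is exact and, for
the k <= 4 designs used here, instantaneous.  Single-response
"maximize" desirability maps a predicted response onto [0, 1] with a
linear ramp between a lower threshold and a target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .designs import FactorDef
from .model import QuadraticFit, predict

__all__ = [
    "OptimumResult",
    "stationary_point",
    "maximize_box",
    "desirability_max",
    "surface_grid",
]


def _classify(eigvals: np.ndarray, tol: float = 1e-10) -> str:
    if np.all(eigvals < -tol):
        return "maximum"
    if np.all(eigvals > tol):
        return "minimum"
    return "saddle"


def stationary_point(fit: QuadraticFit) -> tuple[np.ndarray, str]:
    """Solve grad Y = 0 analytically; classify by Hessian eigenvalues.

    Returns ``(coded point, nature)`` with nature one of
    {"maximum", "minimum", "saddle"}.  Raises for a singular Hessian
    (a ridge system, out of scope here).
    """
    H = fit.hessian()
    b = fit.beta_lin
    try:
        x = np.linalg.solve(2.0 * H, -b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular Hessian: the surface has a stationary ridge; "
            "ridge analysis is out of scope"
        ) from exc
    return x, _classify(np.linalg.eigvalsh(H))


@dataclass
class OptimumResult:
    """Outcome of a box-constrained surface maximisation."""

    argmax_coded: np.ndarray
    argmax_actual: Optional[np.ndarray]  # raw decoded values
    argmax_actual_bench: Optional[np.ndarray]  # clamp floors applied
    y_max: float
    nature: str
    on_boundary: np.ndarray  # per-factor bool flags
    desirability: Optional[float] = None


def maximize_box(
    fit: QuadraticFit,
    lo: Sequence[float] | float = -1.0,
    hi: Sequence[float] | float = 1.0,
    factors: Optional[Sequence[FactorDef]] = None,
    desirability_target: Optional[float] = None,
    desirability_low: float = 0.0,
) -> OptimumResult:
    """Exact maximum of the quadratic over the coded box [lo, hi]^k.

    Every face of the box is a lower-dimensional quadratic problem: fix
    the bound coordinates, solve the stationary system in the free
    coordinates, keep the candidate if it is feasible.  Vertices are the
    all-fixed configurations, so the candidate set is exhaustive and the
    returned maximum is exact.  Ties are broken toward the smallest
    lexicographic coded coordinates for determinism.

    When ``factors`` are supplied the optimum is also reported in actual
    units, both raw and bench-clamped.  When ``desirability_target`` is
    given the single-response maximize-ramp desirability of the optimum
    is attached.
    """
    k = fit.k
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (k,)).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (k,)).copy()
    if not np.all(lo < hi):
        raise ValueError("need lo < hi componentwise")

    H = fit.hessian()
    b = fit.beta_lin

    candidates: list[np.ndarray] = []
    for conf in itertools.product((-1, 0, 1), repeat=k):
        x = np.where(np.array(conf) < 0, lo, hi).astype(float)
        free = [i for i in range(k) if conf[i] == 0]
        if free:
            fixed = [i for i in range(k) if conf[i] != 0]
            Hff = 2.0 * H[np.ix_(free, free)]
            rhs = -(b[free] + (2.0 * H[np.ix_(free, fixed)] @ x[fixed]
                               if fixed else 0.0))
            try:
                xf = np.linalg.solve(Hff, rhs)
            except np.linalg.LinAlgError:
                continue  # flat face: its best point lies on sub-faces
            if np.any(xf < lo[free] - 1e-12) or np.any(xf > hi[free] + 1e-12):
                continue
            x[free] = np.clip(xf, lo[free], hi[free])
        candidates.append(x)

    values = np.array([predict(fit, x) for x in candidates])
    best_val = values.max()
    ties = [candidates[i] for i in np.flatnonzero(values >= best_val - 1e-12)]
    best = min(ties, key=lambda v: tuple(v))

    _, nature = _safe_nature(fit)
    on_boundary = (np.abs(best - lo) <= 1e-9) | (np.abs(best - hi) <= 1e-9)

    actual = actual_bench = None
    if factors is not None:
        actual = np.array([f.decode(c) for f, c in zip(factors, best)])
        actual_bench = np.array(
            [f.decode(c, for_bench=True) for f, c in zip(factors, best)]
        )

    des = None
    if desirability_target is not None:
        des = desirability_max(float(best_val), desirability_low,
                               desirability_target)

    return OptimumResult(
        argmax_coded=best,
        argmax_actual=actual,
        argmax_actual_bench=actual_bench,
        y_max=float(best_val),
        nature=nature,
        on_boundary=on_boundary,
        desirability=des,
    )


def _safe_nature(fit: QuadraticFit) -> tuple[Optional[np.ndarray], str]:
    try:
        return stationary_point(fit)
    except ValueError:
        return None, "degenerate"


def desirability_max(y_pred: float, low: float, target: float) -> float:
    """Single-response "maximize" desirability: 0 below ``low``, 1 at or
    above ``target``, linear ramp in between."""
    if target <= low:
        raise ValueError("desirability target must exceed low")
    if y_pred <= low:
        return 0.0
    if y_pred >= target:
        return 1.0
    return (y_pred - low) / (target - low)


def surface_grid(
    fit: QuadraticFit,
    axis_i: int,
    axis_j: int,
    fixed: Optional[Sequence[float]] = None,
    resolution: int = 41,
    span: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Predicted-response grid over two coded axes for contour/3D export.

    ``fixed`` gives the coded values of the remaining k-2 factors (in
    factor order, defaults to all zero).  Returns a long-format
    DataFrame with columns ``xi, xj, y``.
    """
    if axis_i == axis_j:
        raise ValueError("grid axes must differ")
    k = fit.k
    others = [m for m in range(k) if m not in (axis_i, axis_j)]
    if fixed is None:
        fixed = np.zeros(len(others))
    fixed = np.asarray(fixed, dtype=float)
    if len(fixed) != len(others):
        raise ValueError(f"need {len(others)} fixed values, got {len(fixed)}")

    ax = np.linspace(span[0], span[1], resolution)
    XI, XJ = np.meshgrid(ax, ax, indexing="ij")
    pts = np.zeros((resolution * resolution, k))
    pts[:, axis_i] = XI.ravel()
    pts[:, axis_j] = XJ.ravel()
    for m, v in zip(others, fixed):
        pts[:, m] = v
    y = predict(fit, pts)
    return pd.DataFrame({"xi": pts[:, axis_i], "xj": pts[:, axis_j], "y": y})
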