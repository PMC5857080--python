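"""Experimental-design generation for response-surface studies.

Factors are handled in *coded* units: an actual bench value ``x`` maps to
``(x - center) / step`` so that the design levels become small integers
(±1 factorial, ±alpha axial, 0 centre).  Central composite designs (CCD)
support second-order surface estimation; Plackett-Burman (PB) two-level
designs screen main effects with few runs.

Some coded settings decode to physically impossible bench values (e.g. a
negative salt concentration at the -2 axial level); such factors carry a
``clamp_floor`` that is applied only when preparing bench instructions,
never in the regression, so the planned coded geometry stays intact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorDef",
    "DesignPoint",
    "Design",
    "code_level",
    "decode_level",
    "make_ccd",
    "make_plackett_burman",
    "pb_effects",
]


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor with its coding geometry.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"pH"`` or ``"NaCl"``.
    units : str
        Actual units, e.g. ``"% w/v"``; purely descriptive.
    center : float
        Actual value at coded level 0.
    step : float
        Actual increment per coded unit; must be positive.
    clamp_floor : float, optional
        Lower bound applied to decoded values *at bench execution only*
        (e.g. 0 for a concentration).  The planned, unclamped value is
        always recoverable with ``for_bench=False``.
    """

    name: str
    units: str = ""
    center: float = 0.0
    step: float = 1.0
    clamp_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(
                f"factor {self.name!r}: step must be > 0, got {self.step}"
            )

    def code(self, actual: float) -> float:
        """Map an actual value to coded units: ``(actual - center) / step``."""
        return (actual - self.center) / self.step

    def decode(self, coded: float, for_bench: bool = False) -> float:
        """Map a coded level back to actual units (``center + coded * step``).

        With ``for_bench=True`` the result is floored at ``clamp_floor``
        when one is defined, mirroring bench practice where a negative
        planned concentration is executed as zero.
        """
        actual = self.center + coded * self.step
        if for_bench and self.clamp_floor is not None:
            actual = max(actual, self.clamp_floor)
        return actual


def code_level(factor: FactorDef, actual: float) -> float:
    """Coded level of ``actual`` under ``factor``'s geometry."""
    return factor.code(actual)


def decode_level(factor: FactorDef, coded: float, for_bench: bool = False) -> float:
    """Actual value at ``coded``; optionally bench-clamped (see FactorDef)."""
    return factor.decode(coded, for_bench=for_bench)


@dataclass
class DesignPoint:
    """A single run: coded and actual factor settings plus its design role."""

    run_order: int
    coded: np.ndarray
    actual: np.ndarray
    role: str  # factorial | axial | center | pb

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)


@dataclass
class Design:
    """An ordered collection of design points over a common factor set."""

    factors: list[FactorDef]
    points: list[DesignPoint]
    kind: str = "custom"  # ccd | plackett_burman | custom

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def coded_matrix(self) -> np.ndarray:
        """(n_runs, k) array of coded levels in run order."""
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([p.actual for p in self.points], dtype=float)

    @property
    def roles(self) -> list[str]:
        return [p.role for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run_order, role, then ``<name>_coded`` and
        ``<name>_actual`` per factor."""
        data: dict[str, object] = {
            "run_order": [p.run_order for p in self.points],
            "role": self.roles,
        }
        coded = self.coded_matrix
        actual = self.actual_matrix
        for j, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = coded[:, j]
            data[f"{f.name}_actual"] = actual[:, j]
        return pd.DataFrame(data)

    def bench_sheet(self) -> pd.DataFrame:
        """Actual-unit run sheet with clamp floors applied (what goes to
        the bench, per factor ``clamp_floor``)."""
        df = pd.DataFrame(
            {
                f.name: [f.decode(p.coded[j], for_bench=True) for p in self.points]
                for j, f in enumerate(self.factors)
            }
        )
        df.insert(0, "run_order", [p.run_order for p in self.points])
        return df


def _points_from_coded(
    factors: Sequence[FactorDef], coded_rows: np.ndarray, roles: Sequence[str]
) -> list[DesignPoint]:
    pts = []
    for i, (row, role) in enumerate(zip(coded_rows, roles), start=1):
        actual = np.array(
            [f.decode(c) for f, c in zip(factors, row)], dtype=float
        )
        pts.append(DesignPoint(run_order=i, coded=np.asarray(row, float),
                               actual=actual, role=role))
    return pts


def make_ccd(
    factors: Sequence[FactorDef],
    alpha: float = 2.0,
    n_center: int = 6,
    shuffle_seed: Optional[int] = None,
) -> Design:
    """Build a central composite design.

    The design concatenates the full 2^k factorial at coded ±1, 2k axial
    (star) points at ±``alpha`` on one axis each, and ``n_center``
    replicated centre points — 2^k + 2k + n_center runs in generation
    order.  ``alpha`` defaults to 2, the axial distance of a four-factor
    design whose coded levels span -2..+2.

    Run randomisation is not simulated; pass ``shuffle_seed`` for a
    seeded random run order.
    """
    k = len(factors)
    if k < 2:
        raise ValueError("a CCD needs at least 2 factors")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    fact = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))

    coded = np.vstack([fact, axial, center])
    roles = (["factorial"] * len(fact) + ["axial"] * len(axial)
             + ["center"] * n_center)

    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(coded))
        coded = coded[order]
        roles = [roles[i] for i in order]

    return Design(list(factors), _points_from_coded(factors, coded, roles),
                  kind="ccd")


# Classical cyclic first rows (the remaining rows are right cyclic shifts,
# closed by an all-minus row).
_PB_FIRST_ROWS: dict[int, str] = {
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
}


def make_plackett_burman(
    factors: Sequence[FactorDef], n_runs: int = 12
) -> Design:
    """Build a two-level Plackett-Burman screening design.

    Supports the cyclic constructions with ``n_runs`` in {8, 12, 16, 20};
    each yields an orthogonal n x (n-1) ±1 matrix.  The first
    ``len(factors)`` columns carry the real factors; the remaining
    columns become *dummy* factors whose apparent effects estimate the
    experimental error (see :func:`pb_effects`).
    """
    if n_runs not in _PB_FIRST_ROWS:
        raise ValueError(
            f"unsupported PB size {n_runs}; supported sizes are "
            f"{sorted(_PB_FIRST_ROWS)}"
        )
    k = len(factors)
    if k > n_runs - 1:
        raise ValueError(
            f"{k} factors need more than {n_runs - 1} PB columns; "
            "use a larger n_runs"
        )

    first = np.array([1.0 if c == "+" else -1.0 for c in _PB_FIRST_ROWS[n_runs]])
    ncol = n_runs - 1
    rows = [np.roll(first, i) for i in range(n_runs - 1)]
    rows.append(-np.ones(ncol))
    coded = np.array(rows)

    all_factors = list(factors) + [
        FactorDef(name=f"dummy{i + 1}", units="", center=0.0, step=1.0)
        for i in range(ncol - k)
    ]
    pts = _points_from_coded(all_factors, coded, ["pb"] * n_runs)
    return Design(all_factors, pts, kind="plackett_burman")


def pb_effects(design: Design, y: Sequence[float]) -> pd.DataFrame:
    """Estimate Plackett-Burman main effects with dummy-column error.

    The main effect of column j is ``mean(y at +1) - mean(y at -1)``.
    Dummy columns carry no real factor, so their apparent effects
    estimate pure noise; the pseudo-standard-error of an effect is
    ``sqrt(mean(dummy_effect^2))`` and each real effect is tested with a
    t statistic on ``n_dummy`` degrees of freedom.  Factors are flagged
    significant at p < 0.05.

    Returns a DataFrame with columns ``factor, effect, is_dummy, t, p,
    significant`` (t/p are NaN when no dummy columns exist).
    """
    y = np.asarray(y, dtype=float)
    if design.kind != "plackett_burman":
        raise ValueError("pb_effects requires a plackett_burman design")
    if len(y) != design.n_runs:
        raise ValueError(
            f"response length {len(y)} != number of runs {design.n_runs}"
        )

    X = design.coded_matrix
    n = design.n_runs
    effects = 2.0 * (X.T @ y) / n  # mean(+1) - mean(-1) for ±1 balanced cols
    is_dummy = np.array([f.name.startswith("dummy") for f in design.factors])

    n_dummy = int(is_dummy.sum())
    if n_dummy > 0:
        pse = float(np.sqrt(np.mean(effects[is_dummy] ** 2)))
    else:
        pse = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effects / pse if pse and pse > 0 else np.full_like(effects, np.nan)
    if n_dummy > 0 and pse > 0:
        p = 2.0 * stats.t.sf(np.abs(t), df=n_dummy)
    else:
        # zero-noise dummies: any nonzero effect is "significant"
        p = np.where(np.abs(effects) > 0, 0.0, 1.0) if n_dummy else np.full(len(effects), np.nan)

    return pd.DataFrame(
        {
            "factor": [f.name for f in design.factors],
            "effect": effects,
            "is_dummy": is_dummy,
            "t": t,
            "p": p,
            "significant": (p < 0.05) & ~is_dummy,
        }
    )
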