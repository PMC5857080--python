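"""Synthetic data generation and packaged study tables.

Two generators exercise the whole pipeline without any external data:

* :func:`simulate_ccd_response` draws central-composite responses from a
  known quadratic truth plus iid Gaussian noise.  The natural noise
  scales for this system are the residual standard deviations of the
  two fitted surfaces (4.17 for the *Pseudomonas* ADL15 surface, 7.50
  for the *Rhodococcus* ADL36 surface), which is what homoscedastic
  Gaussian noise at those SDs emulates.
* :func:`simulate_chromatograms` builds C8-C20 *n*-alkane peak ladders
  for an abiotic control and a degraded sample with specified
  per-alkane area reductions.  Retention times follow a linear model in
  carbon number (2.0 min + 0.9 min per carbon by default) — a
  documented convention, since no retention times are published for
  this system.

:func:`load_fixture` exposes the published study tables packaged with
the library: the four-factor coding geometry (pH, temperature, diesel,
NaCl), the two 30-run CCD response tables with their printed predicted
columns, and the two printed regression equations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .designs import Design, FactorDef, make_ccd
from .gc import Peak, PeakTable
from .model import QuadraticFit, ResponseSet, predict, term_labels

__all__ = [
    "SimulationSpec",
    "ChromSimSpec",
    "CCDTable",
    "simulate_ccd_response",
    "simulate_chromatograms",
    "load_fixture",
    "FIXTURE_NAMES",
]

ALKANES = [f"n-C{c}" for c in range(8, 21)]  # C8..C20 ladder


@dataclass
class SimulationSpec:
    """Recipe for a synthetic CCD response set.

    ``true_model`` holds the generating quadratic surface; ``noise_sd``
    the homoscedastic Gaussian response noise in response units
    (percentage points here).  A fixed seed makes the output
    byte-identical.
    """

    true_model: QuadraticFit
    noise_sd: float
    factors: list[FactorDef]
    n_center: int = 6
    alpha: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_ccd_response(spec: SimulationSpec) -> tuple[Design, ResponseSet]:
    """Generate a CCD and a noisy response drawn from the true surface."""
    design = make_ccd(spec.factors, alpha=spec.alpha, n_center=spec.n_center)
    mu = predict(spec.true_model, design.coded_matrix)
    rng = np.random.default_rng(spec.seed)
    y = mu + rng.normal(0.0, spec.noise_sd, size=len(mu))
    return design, ResponseSet(design=design, y=y, label="simulated")


@dataclass
class ChromSimSpec:
    """Recipe for a control/sample/standard chromatogram triple.

    ``control_areas`` maps alkane labels to abiotic-control peak areas;
    ``reductions`` maps alkanes to the fraction of area lost in the
    sample (0 = untouched, 1 = fully degraded).  ``area_noise_cv`` is a
    relative (coefficient-of-variation) Gaussian noise on sample areas.
    Retention times are ``rt_intercept + rt_per_carbon * carbon_number``.
    """

    control_areas: dict[str, float]
    reductions: dict[str, float]
    area_noise_cv: float = 0.0
    rt_intercept: float = 2.0  # min
    rt_per_carbon: float = 0.9  # min per carbon
    seed: int = 0

    def __post_init__(self) -> None:
        for a, r in self.reductions.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reduction for {a} outside [0, 1]: {r}")
        for a, v in self.control_areas.items():
            if v <= 0:
                raise ValueError(f"control area for {a} must be > 0: {v}")

    def rt_of(self, alkane: str) -> float:
        carbon = int(alkane.split("C")[-1])
        return self.rt_intercept + self.rt_per_carbon * carbon


def simulate_chromatograms(
    spec: ChromSimSpec,
) -> tuple[PeakTable, PeakTable, PeakTable]:
    """Return (control, sample, standard) peak tables.

    The control carries the specified areas; the sample carries
    ``control * (1 - reduction) * (1 + noise)`` with noise drawn as
    Gaussian with SD ``area_noise_cv`` (clipped at -0.99 so areas stay
    positive); the standard is the ladder with unit areas.
    """
    rng = np.random.default_rng(spec.seed)
    std = PeakTable(
        sample_id="standard",
        peaks=[Peak(rt=spec.rt_of(a), area=1.0, label=a) for a in ALKANES],
        kind="standard",
    )
    control = PeakTable(
        sample_id="abiotic_control",
        peaks=[Peak(rt=spec.rt_of(a), area=v)
               for a, v in spec.control_areas.items()],
        kind="abiotic_control",
    )
    sample_peaks = []
    for a, v in spec.control_areas.items():
        red = spec.reductions.get(a, 0.0)
        noise = rng.normal(0.0, spec.area_noise_cv) if spec.area_noise_cv else 0.0
        area = v * (1.0 - red) * (1.0 + max(noise, -0.99))
        if area > 0:  # fully degraded alkanes vanish from the sample
            sample_peaks.append(Peak(rt=spec.rt_of(a), area=area))
    sample = PeakTable(sample_id="sample", peaks=sample_peaks, kind="sample")
    return control, sample, std


# ---------------------------------------------------------------------------
# packaged fixtures

FIXTURE_NAMES = (
    "table1_factors",
    "table2_adl15",
    "table4_adl36",
    "eq_adl15",
    "eq_adl36",
)

_MINUS = "−"  # typography normalised at load time


class CCDTable(NamedTuple):
    """A published 30-run CCD table: design, observed response, and the
    predicted column as printed."""

    design: Design
    response: ResponseSet
    predicted: np.ndarray


def _data_text(fname: str) -> str:
    ref = resources.files("rsmdeg.data").joinpath(fname)
    text = ref.read_text(encoding="utf-8")
    _verify_checksum(fname, text)
    return text.replace(_MINUS, "-")


def _verify_checksum(fname: str, text: str) -> None:
    manifest = resources.files("rsmdeg.data").joinpath("MANIFEST.sha256")
    for line in manifest.read_text().splitlines():
        digest, name = line.split()
        if name == fname:
            actual = hashlib.sha256(text.encode("utf-8")).hexdigest()
            if actual != digest:
                raise RuntimeError(f"packaged fixture {fname} is corrupted")
            return
    raise RuntimeError(f"fixture {fname} missing from checksum manifest")


def _load_factors() -> list[FactorDef]:
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("table1_factors.csv")))
    return [
        FactorDef(
            name=str(r["name"]),
            units="" if pd.isna(r["units"]) else str(r["units"]),
            center=float(r["center"]),
            step=float(r["step"]),
            clamp_floor=None if pd.isna(r["clamp_floor"])
            else float(r["clamp_floor"]),
        )
        for _, r in df.iterrows()
    ]


def _load_ccd_table(fname: str) -> CCDTable:
    from io import StringIO

    from .designs import DesignPoint

    factors = _load_factors()
    df = pd.read_csv(StringIO(_data_text(fname)))
    points = []
    for _, r in df.iterrows():
        actual = np.array([float(r[f"{f.name}_actual"]) for f in factors])
        coded = np.array([f.code(a) for f, a in zip(factors, actual)])
        role = ("center" if np.allclose(coded, 0)
                else "axial" if np.sum(coded != 0) == 1
                else "factorial")
        points.append(DesignPoint(run_order=int(r["run_order"]),
                                  coded=coded, actual=actual, role=role))
    design = Design(factors=factors, points=points, kind="ccd")
    response = ResponseSet(design=design,
                           y=df["experimental"].to_numpy(float),
                           label="dodecane mineralisation (%)")
    return CCDTable(design=design, response=response,
                    predicted=df["predicted"].to_numpy(float))


def _load_equation(fname: str) -> QuadraticFit:
    payload = json.loads(_data_text(fname))
    k = int(payload["k"])
    coefs = payload["coefficients"]
    ordered = [coefs[t] for t in term_labels(k)]
    return QuadraticFit.from_coefficients(ordered, k=k)


def load_fixture(name: str):
    """Load a packaged study table by name.

    ``table1_factors`` -> list of FactorDef; ``table2_adl15`` /
    ``table4_adl36`` -> :class:`CCDTable`; ``eq_adl15`` / ``eq_adl36``
    -> :class:`~rsmdeg.model.QuadraticFit` built from the printed
    coded-unit equation (no residual diagnostics).
    """
    if name == "table1_factors":
        return _load_factors()
    if name in ("table2_adl15", "table4_adl36"):
        return _load_ccd_table(f"{name}.csv")
    if name in ("eq_adl15", "eq_adl36"):
        return _load_equation(f"{name}.json")
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
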