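"""Chromatogram peak-table handling and biodegradation efficiency (BE).

GC-FID peak tables (retention time, area) from a culture extract and an
abiotic control are aligned to an *n*-alkane standard ladder (C8-C20)
by retention time, and the loss of each alkane is quantified as

    BE(%) = 100 - (A_s * 100 / A_ac)

where A_s is the peak area in the sample and A_ac the area in the
abiotic control.  Raw chromatogram processing (baseline, peak picking,
integration) is out of scope; inputs are already-integrated peak
tables, typically CSV with columns ``rt_min, area[, label]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakTable",
    "BEResult",
    "match_ladder",
    "be_percent",
    "be_table",
]

DEFAULT_RT_TOL = 0.05  # minutes


@dataclass(frozen=True)
class Peak:
    """One integrated chromatogram peak."""

    rt: float  # retention time, minutes
    area: float  # detector units
    label: Optional[str] = None  # e.g. "n-C12"

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"retention time must be >= 0, got {self.rt}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass
class PeakTable:
    """Peaks of one injection, sorted by retention time."""

    sample_id: str
    peaks: list[Peak]
    kind: str = "sample"  # abiotic_control | sample | standard

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)
        labels = [p.label for p in self.peaks if p.label is not None]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{self.sample_id}: duplicate peak labels")

    def labelled(self) -> dict[str, Peak]:
        return {p.label: p for p in self.peaks if p.label is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rt_min": [p.rt for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "label": [p.label for p in self.peaks],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "",
                   kind: str = "sample") -> "PeakTable":
        peaks = [
            Peak(
                rt=float(r.rt_min),
                area=float(r.area),
                label=(None if "label" not in df.columns
                       or pd.isna(r.label) or r.label == "" else str(r.label)),
            )
            for r in df.itertuples()
        ]
        return cls(sample_id=sample_id, peaks=peaks, kind=kind)

    @classmethod
    def read_csv(cls, path, sample_id: Optional[str] = None,
                 kind: str = "sample") -> "PeakTable":
        df = pd.read_csv(path)
        if not {"rt_min", "area"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns rt_min, area")
        return cls.from_frame(df, sample_id=sample_id or str(path), kind=kind)


def match_ladder(peaks: PeakTable, standard: PeakTable,
                 rt_tol: float = DEFAULT_RT_TOL) -> PeakTable:
    """Label peaks by nearest standard-ladder retention time.

    Each alkane label is assigned at most once: among the sample peaks
    within ``rt_tol`` of a standard peak, the nearest wins; an exact
    distance tie goes to the earlier-eluting peak (with a warning).
    Unmatched peaks keep ``label=None``.  The result is label-complete
    and permutation-invariant to input peak order.
    """
    std = standard.labelled()
    if len(std) != len(standard.peaks):
        raise ValueError("standard ladder must have a label on every peak")

    # candidate (distance, sample_rt, sample_idx, label) sorted globally so
    # that nearest pairs are assigned first
    cands = []
    for label, sp in std.items():
        for i, pk in enumerate(peaks.peaks):
            d = abs(pk.rt - sp.rt)
            if d <= rt_tol:
                cands.append((d, pk.rt, i, label))
    cands.sort()

    assigned_labels: set[str] = set()
    assigned_peaks: dict[int, str] = {}
    for d, rt, i, label in cands:
        if label in assigned_labels or i in assigned_peaks:
            continue
        tied = [c for c in cands
                if c[3] == label and c[0] == d and c[2] != i
                and c[2] not in assigned_peaks]
        if tied:
            warnings.warn(
                f"peaks at rt {rt:.4f} and {tied[0][1]:.4f} are "
                f"equidistant from standard {label}; earlier rt wins"
            )
        assigned_labels.add(label)
        assigned_peaks[i] = label

    # any prior labels are discarded: labels reflect this matching only
    new_peaks = [
        replace(pk, label=assigned_peaks.get(i))
        for i, pk in enumerate(peaks.peaks)
    ]
    return PeakTable(sample_id=peaks.sample_id, peaks=new_peaks,
                     kind=peaks.kind)


def be_percent(a_s: float, a_ac: float) -> float:
    """Biodegradation efficiency: ``100 - a_s * 100 / a_ac``.

    Equal areas give 0, a vanished peak gives 100; a grown peak gives a
    negative value (reported, not clipped).  Requires a positive control
    area.
    """
    if a_ac <= 0:
        raise ValueError(f"abiotic-control area must be > 0, got {a_ac}")
    if a_s < 0:
        raise ValueError(f"sample area must be >= 0, got {a_s}")
    return 100.0 - (a_s * 100.0 / a_ac)


@dataclass
class BEResult:
    """Per-alkane and total biodegradation efficiency."""

    rows: pd.DataFrame  # alkane, a_s, a_ac, be_percent, flagged_negative
    total_be_percent: float

    def be(self, alkane: str) -> float:
        sel = self.rows.loc[self.rows["alkane"] == alkane, "be_percent"]
        if sel.empty:
            raise KeyError(alkane)
        return float(sel.iloc[0])


def be_table(sample: PeakTable, control: PeakTable, standard: PeakTable,
             rt_tol: float = DEFAULT_RT_TOL) -> BEResult:
    """Per-alkane BE for every alkane present in the abiotic control.

    Both tables are first matched to the standard ladder.  Alkanes whose
    peak is absent from the sample score BE = 100 (complete removal);
    alkanes found in the sample but not the control are excluded with a
    warning (no reference area).  The total BE pools areas over the
    control's alkanes: ``100 - 100 * sum(A_s) / sum(A_ac)``.
    """
    s = match_ladder(sample, standard, rt_tol).labelled()
    c = match_ladder(control, standard, rt_tol).labelled()

    orphans = sorted(set(s) - set(c))
    if orphans:
        warnings.warn(
            f"alkanes present in sample but not control, excluded: "
            f"{', '.join(orphans)}"
        )

    order = [p.label for p in standard.peaks if p.label in c]
    recs = []
    tot_s = tot_ac = 0.0
    for alk in order:
        a_ac = c[alk].area
        a_s = s[alk].area if alk in s else 0.0
        be = be_percent(a_s, a_ac)
        recs.append(
            {"alkane": alk, "a_s": a_s, "a_ac": a_ac, "be_percent": be,
             "flagged_negative": be < 0}
        )
        tot_s += a_s
        tot_ac += a_ac

    rows = pd.DataFrame(recs,
                        columns=["alkane", "a_s", "a_ac", "be_percent",
                                 "flagged_negative"])
    total = be_percent(tot_s, tot_ac) if tot_ac > 0 else float("nan")
    return BEResult(rows=rows, total_be_percent=total)
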