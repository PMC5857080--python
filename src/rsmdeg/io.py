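"""CSV/YAML/JSON interchange and report rendering.

CSV is the interchange format throughout: designs travel as
``run_order, role, <name>_coded, <name>_actual [, response]`` tables,
factor configs as YAML/JSON lists of ``{name, units, center, step,
clamp_floor}``, and ANOVA reports as aligned text (mirroring the
classical RSM software layout) or round-trippable JSON.  Unicode minus
signs (U+2212) are normalised to ASCII on input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .designs import Design, DesignPoint, FactorDef
from .model import AnovaReport, AnovaRow, FitStats, QuadraticFit, ResponseSet

__all__ = [
    "read_factors",
    "write_factors",
    "read_design_csv",
    "write_design_csv",
    "write_report",
    "report_text",
    "report_dict",
    "report_from_dict",
    "fit_to_dict",
    "fit_from_dict",
]

_MINUS = "−"
CODING_TOL = 1e-6


def read_factors(path: Union[str, Path]) -> list[FactorDef]:
    """Read a factor config (YAML or JSON list of factor mappings)."""
    text = Path(path).read_text(encoding="utf-8").replace(_MINUS, "-")
    entries = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: expected a non-empty list of factors")
    out = []
    for i, e in enumerate(entries):
        try:
            out.append(
                FactorDef(
                    name=str(e["name"]),
                    units=str(e.get("units", "") or ""),
                    center=float(e["center"]),
                    step=float(e["step"]),
                    clamp_floor=(None if e.get("clamp_floor") in (None, "")
                                 else float(e["clamp_floor"])),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad factor entry {i + 1}: {exc}") from exc
    return out


def write_factors(factors: list[FactorDef], path: Union[str, Path]) -> None:
    payload = [
        {"name": f.name, "units": f.units, "center": f.center,
         "step": f.step, "clamp_floor": f.clamp_floor}
        for f in factors
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _read_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    if raw.dtype == object:
        raw = raw.astype(str).str.replace(_MINUS, "-", regex=False)
    vals = pd.to_numeric(raw, errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # 1-based + header line
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} at line {row}"
        )
    return vals.to_numpy(float)


def read_design_csv(
    path: Union[str, Path],
    factors: Optional[list[FactorDef]] = None,
    response: Optional[str] = None,
) -> tuple[Design, Optional[ResponseSet]]:
    """Read a design CSV (schema written by :func:`write_design_csv`).

    With ``factors`` given, the coded and actual columns are
    cross-validated against the coding geometry (tolerance 1e-6, errors
    name the offending row).  ``response`` selects an optional response
    column returned as a :class:`ResponseSet`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no runs (empty file)") from exc
    if df.empty:
        raise ValueError(f"{path}: no runs")

    if factors is None:
        names = [c[: -len("_coded")] for c in df.columns if c.endswith("_coded")]
        if not names:
            raise ValueError(f"{path}: no <name>_coded columns found")
        factors = [FactorDef(name=n) for n in names]
        infer_actual = False
    else:
        infer_actual = True

    for f in factors:
        if f"{f.name}_coded" not in df.columns:
            raise ValueError(f"{path}: missing column {f.name}_coded")

    coded = np.column_stack(
        [_read_numeric(df, f"{f.name}_coded", path) for f in factors]
    )
    if all(f"{f.name}_actual" in df.columns for f in factors):
        actual = np.column_stack(
            [_read_numeric(df, f"{f.name}_actual", path) for f in factors]
        )
        if infer_actual:
            for j, f in enumerate(factors):
                expect = np.array([f.decode(c) for c in coded[:, j]])
                bad = np.flatnonzero(np.abs(expect - actual[:, j]) > CODING_TOL)
                if bad.size:
                    raise ValueError(
                        f"{path}: coded/actual mismatch for factor "
                        f"{f.name!r} at data row {bad[0] + 1}: coded "
                        f"{coded[bad[0], j]} decodes to {expect[bad[0]]}, "
                        f"file has {actual[bad[0], j]}"
                    )
    else:
        actual = np.array(
            [[f.decode(c) for f, c in zip(factors, row)] for row in coded]
        )

    run_order = (
        _read_numeric(df, "run_order", path).astype(int)
        if "run_order" in df.columns
        else np.arange(1, len(df) + 1)
    )
    roles = (df["role"].astype(str).tolist() if "role" in df.columns
             else ["custom"] * len(df))

    points = [
        DesignPoint(run_order=int(run_order[i]), coded=coded[i],
                    actual=actual[i], role=roles[i])
        for i in range(len(df))
    ]
    design = Design(factors=factors, points=points, kind="custom")

    rs = None
    if response is not None:
        if response not in df.columns:
            raise ValueError(f"{path}: missing response column {response!r}")
        rs = ResponseSet(design=design,
                         y=_read_numeric(df, response, path),
                         label=response)
    return design, rs


def write_design_csv(
    design: Design,
    path: Union[str, Path],
    response: Optional[ResponseSet] = None,
) -> None:
    df = design.to_frame()
    if response is not None:
        df[response.label] = response.y
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ANOVA report rendering


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return ""
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def _sig_mark(row: AnovaRow) -> str:
    if row.significant is None:
        return ""
    return "*" if row.significant else "**"


def report_text(report: AnovaReport) -> str:
    """Aligned-text ANOVA table with significance stars and the fit
    statistics footer ('*' significant at p < 0.05, '**' not)."""
    header = f"{'Source':<14}{'SS':>12}{'df':>4}{'MS':>12}{'F':>10}{'p':>12}  "
    lines = [header, "-" * len(header)]

    def fmt(row: AnovaRow) -> str:
        f = "" if row.f is None else f"{row.f:.2f}"
        ms = "" if np.isnan(row.ms) else f"{row.ms:.2f}"
        return (f"{row.term:<14}{row.ss:>12.2f}{row.df:>4}{ms:>12}"
                f"{f:>10}{_fmt_p(row.p):>12}  {_sig_mark(row)}")

    lines.append(fmt(report.model_row))
    lines.extend(fmt(r) for r in report.rows)
    lines.append(fmt(report.residual_row))
    if report.lack_of_fit_row is not None:
        lines.append(fmt(report.lack_of_fit_row))
        lines.append(fmt(report.pure_error_row))
    lines.append(fmt(report.cor_total_row))

    s = report.fit
    press = "n/a" if s.press is None else f"{s.press:.2f}"
    pred = "n/a" if s.pred_r2 is None else f"{s.pred_r2:.4f}"
    lines += [
        "",
        f"Standard deviation {s.std_dev:10.2f}    R2           {s.r2:8.4f}",
        f"Mean               {s.mean:10.2f}    Adjusted R2  {s.adj_r2:8.4f}",
        f"C.V. %             {s.cv_percent:10.2f}    Predicted R2 {pred:>8}",
        f"PRESS              {press:>10}    Adeq precision {s.adeq_precision:.3f}",
    ]
    return "\n".join(lines)


def _row_dict(row: Optional[AnovaRow]) -> Optional[dict]:
    if row is None:
        return None
    return {
        "term": row.term, "ss": row.ss, "df": row.df,
        "ms": None if row.ms is None or np.isnan(row.ms) else row.ms,
        "f": row.f, "p": row.p, "significant": row.significant,
    }


def report_dict(report: AnovaReport) -> dict:
    s = report.fit
    return {
        "rows": [_row_dict(r) for r in report.rows],
        "model": _row_dict(report.model_row),
        "residual": _row_dict(report.residual_row),
        "lack_of_fit": _row_dict(report.lack_of_fit_row),
        "pure_error": _row_dict(report.pure_error_row),
        "cor_total": _row_dict(report.cor_total_row),
        "fit": {
            "std_dev": s.std_dev, "mean": s.mean,
            "cv_percent": s.cv_percent, "r2": s.r2, "adj_r2": s.adj_r2,
            "pred_r2": s.pred_r2, "press": s.press,
            "adeq_precision": s.adeq_precision,
        },
    }


def _row_from_dict(d: Optional[dict]) -> Optional[AnovaRow]:
    if d is None:
        return None
    return AnovaRow(term=d["term"], ss=d["ss"], df=d["df"],
                    ms=d["ms"] if d["ms"] is not None else np.nan,
                    f=d["f"], p=d["p"], significant=d["significant"])


def report_from_dict(d: dict) -> AnovaReport:
    return AnovaReport(
        rows=[_row_from_dict(r) for r in d["rows"]],
        model_row=_row_from_dict(d["model"]),
        residual_row=_row_from_dict(d["residual"]),
        lack_of_fit_row=_row_from_dict(d["lack_of_fit"]),
        pure_error_row=_row_from_dict(d["pure_error"]),
        cor_total_row=_row_from_dict(d["cor_total"]),
        fit=FitStats(**d["fit"]),
    )


def write_report(report: AnovaReport, path: Union[str, Path],
                 format: str = "text",
                 metadata: Optional[dict] = None) -> None:
    """Write an ANOVA report as aligned text or round-trippable JSON."""
    path = Path(path)
    if format == "text":
        path.write_text(report_text(report) + "\n")
    elif format == "json":
        payload = report_dict(report)
        if metadata:
            payload["metadata"] = metadata
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def fit_to_dict(fit: QuadraticFit) -> dict:
    return {
        "k": fit.k,
        "coefficients": dict(zip(fit.term_order, fit.coefficients)),
        "mse": fit.mse,
        "df_resid": fit.df_resid,
        "residuals": None if fit.residuals is None else list(fit.residuals),
        "hat_diag": None if fit.hat_diag is None else list(fit.hat_diag),
    }


def fit_from_dict(d: dict) -> QuadraticFit:
    from .model import term_labels

    k = int(d["k"])
    coefs = [d["coefficients"][t] for t in term_labels(k)]
    fit = QuadraticFit.from_coefficients(coefs, k=k)
    fit.mse = d.get("mse")
    fit.df_resid = d.get("df_resid")
    if d.get("residuals") is not None:
        fit.residuals = np.asarray(d["residuals"], float)
    if d.get("hat_diag") is not None:
        fit.hat_diag = np.asarray(d["hat_diag"], float)
    return fit
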