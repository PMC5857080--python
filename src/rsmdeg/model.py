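"""Second-order response-surface model fitting and ANOVA diagnostics.

The response (here, percentage *n*-dodecane mineralisation averaged over
triplicate flasks) is regressed on the coded factor levels with the full
quadratic polynomial

    Y = b0 + sum_i b_i X_i + sum_i b_ii X_i^2 + sum_{i<j} b_ij X_i X_j

by ordinary least squares.  The ANOVA report mirrors the output of the
classical response-surface packages: partial (extra-sum-of-squares)
per-term tests, a lack-of-fit / pure-error split from replicated runs,
and the usual fit statistics (R2 family, PRESS via hat diagonals,
coefficient of variation, adequate precision).

All regression arithmetic is in coded units; planned coded levels are
used even where the bench execution clamped an impossible actual value
(the clamp is a bench convenience, not part of the design geometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .designs import Design

__all__ = [
    "QuadraticFit",
    "ResponseSet",
    "AnovaRow",
    "FitStats",
    "AnovaReport",
    "term_labels",
    "build_model_matrix",
    "fit_quadratic",
    "predict",
    "anova",
    "fit_summary",
]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def term_labels(k: int) -> list[str]:
    """Canonical term order: Intercept, A..;, A^2..; then AB, AC, ... (i<j).

    Factors are lettered A, B, C, ... following design-of-experiments
    convention (requires k <= 26).
    """
    if k > len(_ALPHABET):
        raise ValueError("factor lettering supports at most 26 factors")
    letters = list(_ALPHABET[:k])
    lin = letters
    quad = [f"{c}^2" for c in letters]
    inter = [
        f"{letters[i]}{letters[j]}" for i in range(k) for j in range(i + 1, k)
    ]
    return ["Intercept"] + lin + quad + inter


@dataclass
class ResponseSet:
    """A response vector aligned with a design's run order."""

    design: Design
    y: np.ndarray
    label: str = "response"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != self.design.n_runs:
            raise ValueError(
                f"response length {len(self.y)} != design runs "
                f"{self.design.n_runs}"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("responses must be finite")


@dataclass
class QuadraticFit:
    """A fitted full-quadratic surface in coded units.

    ``beta_int`` is ordered lexicographically over pairs (i<j):
    AB, AC, AD, BC, BD, CD for k = 4.  Residual diagnostics are None for
    surfaces constructed directly from published coefficients rather
    than fitted to data.
    """

    k: int
    beta0: float
    beta_lin: np.ndarray
    beta_quad: np.ndarray
    beta_int: np.ndarray
    residuals: Optional[np.ndarray] = None
    hat_diag: Optional[np.ndarray] = None
    mse: Optional[float] = None
    df_resid: Optional[int] = None

    def __post_init__(self) -> None:
        self.beta_lin = np.asarray(self.beta_lin, dtype=float)
        self.beta_quad = np.asarray(self.beta_quad, dtype=float)
        self.beta_int = np.asarray(self.beta_int, dtype=float)
        if len(self.beta_lin) != self.k or len(self.beta_quad) != self.k:
            raise ValueError("need k linear and k quadratic coefficients")
        if len(self.beta_int) != self.k * (self.k - 1) // 2:
            raise ValueError("need k(k-1)/2 interaction coefficients")

    @property
    def term_order(self) -> list[str]:
        return term_labels(self.k)

    @property
    def n_terms(self) -> int:
        """p = 1 + 2k + k(k-1)/2 (15 for k = 4)."""
        return 1 + 2 * self.k + self.k * (self.k - 1) // 2

    @property
    def coefficients(self) -> np.ndarray:
        """All p coefficients in canonical term order."""
        return np.concatenate(
            [[self.beta0], self.beta_lin, self.beta_quad, self.beta_int]
        )

    def hessian(self) -> np.ndarray:
        """Symmetric Hessian/2 matrix H with Y = b0 + b.x + x'Hx:
        H_ii = beta_ii, H_ij = beta_ij / 2."""
        H = np.diag(self.beta_quad).astype(float)
        idx = 0
        for i in range(self.k):
            for j in range(i + 1, self.k):
                H[i, j] = H[j, i] = self.beta_int[idx] / 2.0
                idx += 1
        return H

    @classmethod
    def from_coefficients(cls, coefs: Sequence[float], k: int) -> "QuadraticFit":
        """Build a surface from p coefficients in canonical term order."""
        coefs = np.asarray(coefs, dtype=float)
        p = 1 + 2 * k + k * (k - 1) // 2
        if len(coefs) != p:
            raise ValueError(f"expected {p} coefficients for k={k}")
        return cls(
            k=k,
            beta0=float(coefs[0]),
            beta_lin=coefs[1 : 1 + k],
            beta_quad=coefs[1 + k : 1 + 2 * k],
            beta_int=coefs[1 + 2 * k :],
        )


def build_model_matrix(coded: np.ndarray | Design) -> np.ndarray:
    """Full-quadratic model matrix (n x p) in canonical term order.

    Column 0 is the intercept; then the k coded levels, their squares,
    and the pairwise products in lexicographic (i<j) order.
    """
    if isinstance(coded, Design):
        coded = coded.coded_matrix
    C = np.asarray(coded, dtype=float)
    if C.ndim == 1:
        C = C.reshape(1, -1)
    n, k = C.shape
    if k < 2:
        raise ValueError("need at least 2 factors")
    cols = [np.ones(n)]
    cols += [C[:, i] for i in range(k)]
    cols += [C[:, i] ** 2 for i in range(k)]
    cols += [C[:, i] * C[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols)


def fit_quadratic(design: Design, response: ResponseSet | Sequence[float]) -> QuadraticFit:
    """Fit the full second-order model by OLS in coded units.

    Raises when the model matrix is rank-deficient (naming the collinear
    terms) or when there are not more runs than terms.
    """
    if not isinstance(response, ResponseSet):
        response = ResponseSet(design=design, y=np.asarray(response, float))
    y = response.y
    X = build_model_matrix(design)
    n, p = X.shape
    k = design.k
    if n <= p:
        raise ValueError(f"need more runs than model terms (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        labels = term_labels(k)
        # identify terms whose removal does not reduce the rank
        collinear = [
            labels[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(
            f"model matrix is rank deficient (rank {rank} < {p}); "
            f"collinear terms: {', '.join(collinear)}"
        )

    ols = sm.OLS(y, X).fit()
    beta = np.asarray(ols.params, dtype=float)
    resid = np.asarray(ols.resid, dtype=float)
    hat = np.asarray(ols.get_influence().hat_matrix_diag, dtype=float)
    df_resid = n - p

    return QuadraticFit(
        k=k,
        beta0=float(beta[0]),
        beta_lin=beta[1 : 1 + k],
        beta_quad=beta[1 + k : 1 + 2 * k],
        beta_int=beta[1 + 2 * k :],
        residuals=resid,
        hat_diag=hat,
        mse=float(resid @ resid) / df_resid,
        df_resid=df_resid,
    )


def predict(fit: QuadraticFit, coded_points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted polynomial at coded points (n x k or length-k)."""
    pts = np.asarray(coded_points, dtype=float)
    one_d = pts.ndim == 1
    if one_d:
        pts = pts.reshape(1, -1)
    if pts.shape[1] != fit.k:
        raise ValueError(
            f"points have {pts.shape[1]} coordinates, model has k={fit.k}"
        )
    out = build_model_matrix(pts) @ fit.coefficients
    return float(out[0]) if one_d else out


@dataclass
class AnovaRow:
    term: str
    ss: float
    df: int
    ms: float
    f: Optional[float]
    p: Optional[float]
    significant: Optional[bool]


@dataclass
class FitStats:
    std_dev: float
    mean: float
    cv_percent: float
    r2: float
    adj_r2: float
    pred_r2: Optional[float]
    press: Optional[float]
    adeq_precision: float


@dataclass
class AnovaReport:
    """Per-term partial-SS ANOVA plus global fit statistics."""

    rows: list[AnovaRow]
    model_row: AnovaRow
    residual_row: AnovaRow
    lack_of_fit_row: Optional[AnovaRow]
    pure_error_row: Optional[AnovaRow]
    cor_total_row: AnovaRow
    fit: FitStats

    def term(self, label: str) -> AnovaRow:
        for r in self.rows:
            if r.term == label:
                return r
        raise KeyError(label)


def _replicate_groups(coded: np.ndarray, tol: float = 1e-9) -> list[np.ndarray]:
    """Indices of runs sharing identical coded rows (within tol)."""
    keys = np.round(coded / tol) * tol
    seen: dict[tuple, list[int]] = {}
    for i, row in enumerate(keys):
        seen.setdefault(tuple(row), []).append(i)
    return [np.array(g) for g in seen.values() if len(g) > 1]


def anova(design: Design, response: ResponseSet | Sequence[float],
          fit: QuadraticFit, alpha: float = 0.05) -> AnovaReport:
    """Build the full ANOVA report for a fitted quadratic surface.

    Per-term sums of squares follow the extra-sum-of-squares (partial,
    Type-III-style) principle: SS(term) is the increase in residual SS
    when that term alone is dropped and the model refitted.  The
    lack-of-fit partition uses replicate groups identified by exact
    equality of coded rows; pure-error SS is the within-group squared
    deviation about group means.  p-values smaller than 1e-4 are
    rendered "< 0.0001" by the report writers but stored exactly.
    """
    if not isinstance(response, ResponseSet):
        response = ResponseSet(design=design, y=np.asarray(response, float))
    y = response.y
    X = build_model_matrix(design)
    n, p = X.shape
    labels = term_labels(design.k)

    if fit.residuals is None or fit.df_resid is None:
        raise ValueError("anova needs a data-fitted QuadraticFit")
    resid = fit.residuals
    ss_res = float(resid @ resid)
    df_res = fit.df_resid
    ms_res = ss_res / df_res

    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    ss_model = ss_tot - ss_res
    df_model = p - 1

    f_model = (ss_model / df_model) / ms_res
    p_model = float(stats.f.sf(f_model, df_model, df_res))

    rows: list[AnovaRow] = []
    for j in range(1, p):  # skip intercept
        Xr = np.delete(X, j, axis=1)
        rr = sm.OLS(y, Xr).fit()
        ss_term = float(rr.ssr - ss_res)
        f_term = ss_term / ms_res
        p_term = float(stats.f.sf(f_term, 1, df_res))
        rows.append(AnovaRow(labels[j], ss_term, 1, ss_term, f_term, p_term,
                             p_term < alpha))

    groups = _replicate_groups(design.coded_matrix)
    lof_row = pe_row = None
    if groups:
        ss_pe = float(sum(np.sum((y[g] - np.mean(y[g])) ** 2) for g in groups))
        df_pe = int(sum(len(g) - 1 for g in groups))
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof = p_lof = None
        lof_row = AnovaRow("Lack of fit", ss_lof, df_lof,
                           ss_lof / df_lof if df_lof else np.nan,
                           f_lof, p_lof,
                           (p_lof < alpha) if p_lof is not None else None)
        pe_row = AnovaRow("Pure error", ss_pe, df_pe,
                          ss_pe / df_pe if df_pe else np.nan, None, None, None)
    else:
        warnings.warn("no replicated runs: lack-of-fit rows omitted")

    return AnovaReport(
        rows=rows,
        model_row=AnovaRow("Model", ss_model, df_model, ss_model / df_model,
                           f_model, p_model, p_model < alpha),
        residual_row=AnovaRow("Residual", ss_res, df_res, ms_res,
                              None, None, None),
        lack_of_fit_row=lof_row,
        pure_error_row=pe_row,
        cor_total_row=AnovaRow("Cor total", ss_tot, n - 1, np.nan,
                               None, None, None),
        fit=fit_summary(design, response, fit),
    )


def fit_summary(design: Design, response: ResponseSet | Sequence[float],
                fit: QuadraticFit) -> FitStats:
    """Global fit statistics: SD, CV%, R2 family, PRESS, adequate precision.

    PRESS is the leave-one-out prediction error sum of squares computed
    from the hat diagonals, ``sum((e_i / (1 - h_ii))^2)``; predicted R2
    is ``1 - PRESS / SS(corrected total)``.  Adequate precision is the
    signal-to-noise measure ``(max yhat - min yhat) / sqrt(p * MSE / n)``
    over the design points.
    """
    if not isinstance(response, ResponseSet):
        response = ResponseSet(design=design, y=np.asarray(response, float))
    y = response.y
    n = design.n_runs
    p = fit.n_terms
    if fit.residuals is None or fit.mse is None or fit.hat_diag is None:
        raise ValueError("fit_summary needs a data-fitted QuadraticFit")

    resid = fit.residuals
    hat = fit.hat_diag
    ss_res = float(resid @ resid)
    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    df_res = fit.df_resid

    sd = float(np.sqrt(fit.mse))
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1))

    if np.any(hat >= 1.0 - 1e-12):
        warnings.warn("leverage >= 1: PRESS undefined, reported as missing")
        press = pred_r2 = None
    else:
        press = float(np.sum((resid / (1.0 - hat)) ** 2))
        pred_r2 = 1.0 - press / ss_tot

    yhat = y - resid
    adeq = float((yhat.max() - yhat.min()) / np.sqrt(p * fit.mse / n))

    return FitStats(
        std_dev=sd,
        mean=ybar,
        cv_percent=100.0 * sd / ybar,
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adeq_precision=adeq,
    )
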