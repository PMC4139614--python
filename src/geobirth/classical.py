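"""Classical (frequentist) analysis: descriptive tests and logistic odds
ratios with Wald intervals, fitted by Newton/IRLS.

These reproduce the survey-report style of analysis: per-factor unadjusted
odds ratios (each one a single-factor logistic fit, equivalently an odds
ratio of category proportions) and a multi-factor adjusted model over the
terms that screened significant univariately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey import Dataset, DesignMatrix, FactorSpec, build_design

__all__ = [
    "FitResult",
    "SeparationError",
    "or_from_props",
    "or_from_counts",
    "fit_logistic_irls",
    "or_table",
    "chi_square_independence",
    "mann_whitney_u",
]


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, last: "FitResult"):
        super().__init__(msg)
        self.last = last


@dataclass(frozen=True)
class FitResult:
    """Converged logistic fit: coefficients on the log-odds scale and the
    Wald covariance (inverse observed information)."""

    coefficients: np.ndarray
    covariance: np.ndarray
    columns: tuple[str, ...]
    converged: bool
    iterations: int
    log_likelihood: float

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def or_from_props(p1: float, p0: float) -> float:
    """Odds ratio of two outcome proportions: (p1/(1-p1)) / (p0/(1-p0))."""
    for p in (p1, p0):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie strictly between 0 and 1")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def or_from_counts(
    a: int, b: int, c: int, d: int, *, continuity: bool = False, level: float = 0.95
) -> tuple[float, float, float]:
    """2x2 table odds ratio ``ad/(bc)`` with a Woolf (log-scale Wald) CI.

    Cells are (exposed event, exposed non-event, unexposed event, unexposed
    non-event).  Zero cells raise unless ``continuity`` adds the Haldane
    +0.5 correction to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(cells == 0):
        if not continuity:
            raise ValueError("zero cell; pass continuity=True for the +0.5 correction")
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt((1 / cells).sum())
    zc = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or)), float(np.exp(log_or - zc * se)), float(np.exp(log_or + zc * se))


def fit_logistic_irls(
    dm: DesignMatrix | tuple[np.ndarray, np.ndarray],
    max_iter: int = 50,
    tol: float = 1e-10,
    columns: tuple[str, ...] | None = None,
) -> FitResult:
    """Newton-Raphson (IRLS) maximum likelihood for logistic regression.

    Stops when the largest score component drops below ``tol`` or the
    relative deviance change does.  Diverging coefficients (|beta| > 30 on
    a dummy-coded design) are flagged as separation.
    """
    if isinstance(dm, DesignMatrix):
        X, y = dm.X, dm.y
        columns = dm.columns
    else:
        y, X = np.asarray(dm[0], dtype=float), np.asarray(dm[1], dtype=float)
        columns = columns or tuple(f"x{j}" for j in range(X.shape[1]))
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix (separation or rank deficiency)")
        beta = beta + step
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        dev = -2 * ll
        if np.max(np.abs(beta)) > 30 or (dev < 1e-6 * n and np.max(np.abs(beta)) > 10):
            raise SeparationError("diverging coefficients: data are (quasi-)separated")
        if np.max(np.abs(score)) < tol or abs(dev_old - dev) < tol * (abs(dev) + 1):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1 - mu), 1e-12, None)
            info = (X * w[:, None]).T @ X
            cov = np.linalg.inv(info)
            return FitResult(beta, cov, tuple(columns), True, it, ll)
        dev_old = dev
    last = FitResult(beta, np.full((p, p), np.nan), tuple(columns), False, max_iter, float("nan"))
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations", last)


def or_table(fit: FitResult, codebook: dict[str, FactorSpec], level: float = 0.95) -> pd.DataFrame:
    """Exponentiate a fit into (term, level, OR, CI, p) rows, with reference
    categories marked ``RC`` (OR fixed at 1)."""
    if not fit.converged:
        raise ValueError("or_table requires a converged fit")
    zc = stats.norm.ppf(0.5 + level / 2)
    se = fit.se()
    by_col = dict(zip(fit.columns, zip(fit.coefficients, se)))
    rows = []
    seen_terms: list[str] = []
    for col in fit.columns:
        if col == "intercept":
            rows.append(_or_row("intercept", "", *by_col[col], zc))
            continue
        term, lev = col[:-1].split("[", 1)
        if term not in seen_terms:
            seen_terms.append(term)
        rows.append(_or_row(term, lev, *by_col[col], zc))
    # append RC markers in codebook order
    for term in seen_terms:
        if term in codebook:
            rows.append({"term": term, "level": codebook[term].reference, "OR": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "reference": True})
    out = pd.DataFrame(rows)
    out["reference"] = out.get("reference", False)
    out["reference"] = out["reference"].fillna(False).astype(bool)
    return out


def _or_row(term: str, lev: str, coef: float, se: float, zc: float) -> dict:
    z = coef / se if se > 0 else np.nan
    with np.errstate(over="ignore"):  # huge Wald bounds on sparse levels exp to inf
        return {
            "term": term,
            "level": lev,
            "OR": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - zc * se)),
            "ci_high": float(np.exp(coef + zc * se)),
            "p_value": float(2 * stats.norm.sf(abs(z))),
            "reference": False,
        }


def univariate_or_tables(ds: Dataset, factors: list[str], level: float = 0.95) -> dict[str, pd.DataFrame]:
    """One single-factor logistic fit per factor (the 'unadjusted' columns)."""
    out = {}
    for f in factors:
        dm = build_design(ds, [f])
        out[f] = or_table(fit_logistic_irls(dm), ds.codebook, level)
    return out


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal row/column")
    expected = np.outer(rows, cols) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return x2, df, float(stats.chi2.sf(x2, df))


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with midranks, tie-corrected normal approximation
    (with continuity correction) and two-sided p-value.
    Returns (U of the first sample, z, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n].sum()
    u = r1 - n * (n + 1) / 2.0
    mu = n * m / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    big_n = n + m
    tie_term = ((counts**3 - counts).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var <= 0:
        raise ValueError("degenerate variance: all pooled values identical")
    z = (u - mu) / np.sqrt(var)
    # continuity-corrected tail (U is integer/half-integer valued)
    z_cc = np.sign(u - mu) * max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z_cc)))
    return float(u), float(z), min(p, 1.0)
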