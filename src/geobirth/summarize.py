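"""Posterior summaries: odds ratios with credible regions, the age-effect
band, and significance-classified province map tables.

Conventions: the point estimate on the odds-ratio scale is
``exp(posterior mean of the log-odds effect)`` (the posterior mean of the
exponential is also reported); credible regions are equal-tailed; a region
effect is classified ``+1`` / ``-1`` when its credible region at the
requested nominal level excludes zero on the log-odds scale (equivalently,
excludes one on the OR scale), else ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import AdjacencyGraph
from .mcmc import PosteriorDraws
from .splines import SplineBasis

__all__ = [
    "EffectSummary",
    "summarize_effect",
    "classify_significance",
    "make_map_table",
    "age_effect_grid",
    "fixed_effect_table",
]

_DEFAULT_LEVELS = (0.80, 0.95)


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one scalar log-odds effect."""

    name: str
    mean: float
    quantiles: dict[float, float]  # probability -> log-odds quantile
    levels: tuple[float, ...]

    @property
    def por(self) -> float:
        return float(np.exp(self.mean))

    def credible_region(self, level: float) -> tuple[float, float]:
        """Equal-tailed CR on the OR scale."""
        lo, hi = self._log_cr(level)
        return float(np.exp(lo)), float(np.exp(hi))

    def _log_cr(self, level: float) -> tuple[float, float]:
        if level not in self.levels:
            raise ValueError(f"level {level} not computed (have {self.levels})")
        a = (1.0 - level) / 2.0
        return self.quantiles[round(a, 10)], self.quantiles[round(1 - a, 10)]


def summarize_effect(
    chain: np.ndarray, name: str = "", levels: tuple[float, ...] = _DEFAULT_LEVELS
) -> EffectSummary:
    """Summarize a pooled chain of log-odds draws at the requested CR levels
    (plus the median); empirical quantiles use linear (type-7) interpolation."""
    x = np.asarray(chain, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty chain")
    for l in levels:
        if not 0.0 < l < 1.0:
            raise ValueError(f"invalid level {l}")
    probs = sorted({0.5, *[round((1 - l) / 2, 10) for l in levels], *[round((1 + l) / 2, 10) for l in levels]})
    qs = np.quantile(x, probs)
    return EffectSummary(name, float(x.mean()), dict(zip(probs, map(float, qs))), tuple(levels))


def classify_significance(summary: EffectSummary, level: float) -> int:
    """+1 if the log-scale CR lies above 0, -1 if below, else 0."""
    lo, hi = summary._log_cr(level)
    if lo > 0:
        return 1
    if hi < 0:
        return -1
    return 0


def make_map_table(
    draws: PosteriorDraws,
    g: AdjacencyGraph | None = None,
    level: float = 0.80,
    total: bool = True,
) -> pd.DataFrame:
    """Per-province posterior OR, CR and significance class.

    ``total=True`` summarizes the total residual region effect (structured +
    unstructured when both were fitted); provinces come out in graph/node
    order.  Columns: province, POR, cr_low, cr_high, class, prob_positive.
    """
    if draws.s is None:
        raise ValueError("fit has no spatial term")
    eff = draws.total_spatial() if total else draws.s
    nodes = g.nodes if g is not None else draws.node_order
    if tuple(nodes) != tuple(draws.node_order):
        raise ValueError("graph nodes do not match the fitted node order")
    pooled = draws.pooled(eff)
    rows = []
    for j, prov in enumerate(nodes):
        summ = summarize_effect(pooled[:, j], prov, levels=(level, 0.95) if level != 0.95 else (0.95,))
        lo, hi = summ.credible_region(level)
        rows.append(
            {
                "province": prov,
                "POR": summ.por,
                "cr_low": lo,
                "cr_high": hi,
                "class": classify_significance(summ, level),
                "prob_positive": float((pooled[:, j] > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def age_effect_grid(
    draws: PosteriorDraws,
    basis: SplineBasis | None = None,
    grid: np.ndarray | None = None,
    level: float = 0.80,
) -> pd.DataFrame:
    """Posterior band of the centered age smooth on an age grid.

    Columns: age, mean, cr_low, cr_high (log-odds scale, centered the same
    way as during sampling).
    """
    if draws.gamma is None:
        raise ValueError("fit has no smooth term")
    basis = basis or draws.basis
    if grid is None:
        grid = np.arange(np.ceil(basis.xmin), np.floor(basis.xmax) + 1)
    grid = np.asarray(grid, dtype=float)
    Bg = basis.design(grid)  # raises outside the span
    f = draws.pooled(draws.gamma) @ Bg.T  # draws x grid
    a = (1 - level) / 2
    lo, hi = np.quantile(f, [a, 1 - a], axis=0)
    return pd.DataFrame({"age": grid, "mean": f.mean(axis=0), "cr_low": lo, "cr_high": hi})


def join_map_geojson(map_table: pd.DataFrame, geojson: dict, key: str = "province") -> dict:
    """Attach map-table columns to GeoJSON features by province code.

    The ``key`` property of each feature is matched against the table's
    ``province`` column; features without a match are left untouched.  The
    input mapping is not modified.
    """
    import copy

    out = copy.deepcopy(geojson)
    rows = map_table.set_index("province")
    for feat in out.get("features", []):
        code = feat.get("properties", {}).get(key)
        if code in rows.index:
            feat["properties"].update(
                {c: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for c, v in rows.loc[code].items()}
            )
    return out


def fixed_effect_table(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior OR table for the fixed effects (intercept included)."""
    pooled = draws.pooled(draws.beta)
    rows = []
    for j, name in enumerate(draws.beta_columns):
        summ = summarize_effect(pooled[:, j], name, levels=(0.80, 0.95))
        lo, hi = summ.credible_region(level)
        rows.append(
            {
                "term": name,
                "POR": summ.por,
                "POR_mean_exp": float(np.exp(pooled[:, j]).mean()),
                "cr_low": lo,
                "cr_high": hi,
                "class": classify_significance(summ, level),
            }
        )
    return pd.DataFrame(rows)
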