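"""Survey records: schema, validation, I/O, subsetting and design matrices.

One row per woman: her province of residence, age in completed years, the
binary outcome (preceding birth interval of at most 24 months), and the
categorical risk factors.  A :class:`Dataset` couples the records with a
codebook of :class:`FactorSpec` entries that fix the admissible levels and
the reference category of each factor; dummy coding in
:func:`build_design` drops the reference level, so every fitted odds ratio is
expressed against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import AdjacencyGraph

__all__ = [
    "FactorSpec",
    "Dataset",
    "DesignMatrix",
    "default_codebook",
    "read_records",
    "write_records",
    "filter_complete",
    "subset_age",
    "crosstab_percent",
    "build_design",
    "add_age_group",
    "RECORD_COLUMNS",
    "AGE_BANDS",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "id", "province", "age_years", "short_interval",
    "residence", "wealth", "education", "contraception", "breastfeeding",
)

#: Five-year age bands used by the classical (tabular) analysis.
AGE_BANDS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")

AGE_MIN, AGE_MAX = 15, 49


@dataclass(frozen=True)
class FactorSpec:
    """Levels and reference category of one categorical factor."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"{self.name}: empty level list")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate levels")
        if self.reference not in self.levels:
            raise ValueError(f"{self.name}: reference {self.reference!r} not a level")

    @property
    def nonreference(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


def default_codebook(provinces: Sequence[str] | None = None) -> dict[str, FactorSpec]:
    """The survey's default coding.

    Reference categories follow the published tables: Kinshasa (lowest
    observed prevalence), urban residence, high household income, secondary+
    education, modern contraception, mixed breastfeeding, oldest age band.
    """
    from .graph import DRC_PROVINCES

    prov = tuple(provinces) if provinces is not None else DRC_PROVINCES
    return {
        "province": FactorSpec("province", prov, prov[0]),
        "residence": FactorSpec("residence", ("urban", "rural"), "urban"),
        "wealth": FactorSpec("wealth", ("low", "middle", "high"), "high"),
        "education": FactorSpec("education", ("none", "primary", "secondary_plus"), "secondary_plus"),
        "contraception": FactorSpec("contraception", ("none", "traditional", "modern"), "modern"),
        "breastfeeding": FactorSpec("breastfeeding", ("never", "exclusive", "mixed"), "mixed"),
        "age_group": FactorSpec("age_group", AGE_BANDS, AGE_BANDS[-1]),
    }


@dataclass(frozen=True)
class Dataset:
    """Validated survey records plus their codebook.

    ``df`` holds one row per record with the columns of ``RECORD_COLUMNS``
    (plus any derived columns such as ``age_group``).  Missing values are
    ``NaN``/``NA``; validity is enforced for non-missing entries only, so a
    Dataset may carry incomplete records until :func:`filter_complete`.
    """

    df: pd.DataFrame
    codebook: dict[str, FactorSpec] = field(default_factory=default_codebook)

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate record ids")

    @property
    def n(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "Dataset":
        return replace(self, df=df.reset_index(drop=True))


def _validate_rows(df: pd.DataFrame, codebook: dict[str, FactorSpec]) -> pd.Series:
    """Boolean mask of rows whose non-missing fields are all admissible."""
    ok = pd.Series(True, index=df.index)
    age = pd.to_numeric(df["age_years"], errors="coerce")
    ok &= age.isna() | ((age >= AGE_MIN) & (age <= AGE_MAX) & (age == age.round()))
    y = pd.to_numeric(df["short_interval"], errors="coerce")
    ok &= y.isna() | y.isin([0, 1])
    for name in ("province", "residence", "wealth", "education", "contraception", "breastfeeding"):
        spec = codebook[name]
        col = df[name]
        ok &= col.isna() | col.isin(spec.levels)
    return ok


def read_records(path: str | Path, codebook: dict[str, FactorSpec] | None = None) -> Dataset:
    """Read a records CSV, keeping only rows that validate.

    Rejected rows are counted and reported through the module logger.
    Missing values may be empty strings or ``NA``.
    """
    codebook = codebook or default_codebook()
    df = pd.read_csv(path, dtype={"id": str}, na_values=["", "NA"], keep_default_na=False)
    missing_cols = set(RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"records file lacks required columns: {sorted(missing_cols)}")
    ok = _validate_rows(df, codebook)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("rejected %d invalid record(s) out of %d", n_bad, len(df))
    df = df.loc[ok].reset_index(drop=True)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce").astype("Int64")
    df["short_interval"] = pd.to_numeric(df["short_interval"], errors="coerce").astype("Int64")
    return Dataset(df, codebook)


def write_records(ds: Dataset, path: str | Path) -> None:
    """Write the records back to CSV (missing fields as empty strings)."""
    ds.df.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


def filter_complete(ds: Dataset) -> Dataset:
    """Listwise deletion: drop records with any missing core field."""
    complete = ds.df[list(RECORD_COLUMNS)].notna().all(axis=1)
    return ds.with_df(ds.df.loc[complete])


def subset_age(ds: Dataset, lo: int, hi: int) -> Dataset:
    """Records with ``lo <= age_years <= hi`` (inclusive both ends)."""
    if lo > hi:
        raise ValueError(f"invalid age bounds ({lo}, {hi})")
    keep = (ds.df["age_years"] >= lo) & (ds.df["age_years"] <= hi)
    return ds.with_df(ds.df.loc[keep.fillna(False)])


def add_age_group(ds: Dataset) -> Dataset:
    """Attach the derived five-year age-band factor."""
    age = ds.df["age_years"].astype(float)
    band = pd.cut(
        age,
        bins=[14, 19, 24, 29, 34, 39, 44, 49],
        labels=list(AGE_BANDS),
    ).astype(object)
    df = ds.df.copy()
    df["age_group"] = band
    return ds.with_df(df)


def crosstab_percent(ds: Dataset, factor: str) -> pd.DataFrame:
    """Per-level count and percentage with a short birth interval.

    Returns one row per codebook level (empty levels kept with ``n = 0`` and
    ``NaN`` percentage), columns ``level``, ``n``, ``percent``.
    """
    if factor not in ds.codebook:
        raise ValueError(f"unknown factor {factor!r}")
    df = ds.df
    if factor not in df.columns:
        raise ValueError(f"factor {factor!r} not present in records (derive it first)")
    spec = ds.codebook[factor]
    rows = []
    for level in spec.levels:
        sub = df.loc[df[factor] == level, "short_interval"]
        n = int(len(sub))
        pct = float(100.0 * sub.astype(float).mean()) if n else float("nan")
        rows.append({"level": level, "n": n, "percent": pct})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignMatrix:
    """Response and dummy-coded fixed-effect design, with the pieces the
    geo-additive model needs kept aside: raw age (for the smooth term) and a
    row-to-graph-node index (for the spatial term)."""

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...]
    term_index: dict[str, tuple[int, ...]]
    age: np.ndarray
    province_index: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row mismatch")


def build_design(
    ds: Dataset,
    terms: Sequence[str],
    graph: AdjacencyGraph | None = None,
) -> DesignMatrix:
    """Dummy-code ``terms`` against their reference categories.

    Column order is deterministic: intercept first, then factors in the given
    order, levels in declared codebook order with the reference dropped.
    ``province_index`` maps each row to the node order of ``graph`` when one
    is supplied (default: codebook province order).
    """
    for t in terms:
        if t not in ds.codebook:
            raise ValueError(f"term {t!r} not in codebook")
    df = ds.df
    if df[["short_interval", "age_years", "province"]].isna().any().any():
        raise ValueError("design matrix requires complete records; run filter_complete first")
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_index: dict[str, tuple[int, ...]] = {"intercept": (0,)}
    for t in terms:
        spec = ds.codebook[t]
        vals = df[t].to_numpy()
        idxs = []
        for level in spec.nonreference:
            idxs.append(len(names))
            cols.append((vals == level).astype(float))
            names.append(f"{t}[{level}]")
        term_index[t] = tuple(idxs)
    node_order = graph.nodes if graph is not None else ds.codebook["province"].levels
    pos = {c: i for i, c in enumerate(node_order)}
    try:
        province_index = np.array([pos[p] for p in df["province"]], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"province code {e} not among graph nodes") from None
    return DesignMatrix(
        y=df["short_interval"].to_numpy(dtype=float),
        X=np.column_stack(cols),
        columns=tuple(names),
        term_index=term_index,
        age=df["age_years"].to_numpy(dtype=float),
        province_index=province_index,
        node_order=tuple(node_order),
    )
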