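"""End-to-end orchestration: data in, report tables out.

``run_pipeline`` executes the full study design on either a supplied records
CSV or a simulated dataset: completeness filtering, the two analysis
populations (all women 15-49 and young women 15-24), descriptive crosstabs,
unadjusted and adjusted classical odds-ratio tables, the Bayesian
geo-additive fit, and the posterior report tables (fixed-effect ORs, the
age-effect band, and the significance-classified province map table).  Every
output is a CSV; a JSON manifest records the configuration, seeds, row
counts and content hashes so reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classical, summarize, survey
from .graph import AdjacencyGraph, default_drc_graph, load_graph
from .mcmc import MCMCConfig, ModelSpec, run_mcmc
from .simulate import default_survey_config, generate
from .splines import SplineBasis
from .survey import Dataset, add_age_group, build_design, filter_complete, read_records, subset_age

__all__ = ["PipelineConfig", "run_pipeline", "compare_tables"]

log = logging.getLogger(__name__)

#: Default adjusted-model term lists (factors that screen significant
#: univariately in the published tables).
ADJUSTED_TERMS = {
    "all": ("province", "residence", "education", "age_group", "contraception"),
    "young": ("province", "wealth", "age_group"),
}

DESCRIPTIVE_FACTORS = (
    "province", "residence", "wealth", "education", "contraception", "breastfeeding", "age_group",
)

BAYES_FIXED_TERMS = ("residence", "wealth", "education", "contraception", "breastfeeding")


@dataclass(frozen=True)
class PipelineConfig:
    """One run of the study.  Exactly one of ``records`` / ``simulate``."""

    out_dir: str | Path
    records: str | Path | None = None
    graph: str | Path | None = None
    simulate: bool = False
    n_records: int = 7172
    seed: int = 0
    populations: tuple[str, ...] = ("all", "young")
    adjusted_terms: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(ADJUSTED_TERMS))
    n_basis_all: int = 20
    n_basis_young: int = 10
    unstructured: bool = True
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 10
    chains: int = 2
    report_levels: tuple[float, float] = (0.80, 0.95)
    stages: tuple[str, ...] = ("classical", "bayes")  # descriptives always run

    def __post_init__(self) -> None:
        if self.simulate == (self.records is not None):
            raise ValueError("exactly one of a records path or simulate=True is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a YAML mapping of the dataclass fields."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("populations", "report_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "adjusted_terms" in raw:
            raw["adjusted_terms"] = {k: tuple(v) for k, v in raw["adjusted_terms"].items()}
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _population(ds: Dataset, which: str) -> Dataset:
    if which == "all":
        return ds
    if which == "young":
        return subset_age(ds, 15, 24)
    raise ValueError(f"unknown population {which!r}")


def _restrict_age_group(ds: Dataset) -> Dataset:
    """Restrict the age-band factor to the bands present, reference = oldest."""
    present = [b for b in survey.AGE_BANDS if (ds.df["age_group"] == b).any()]
    cb = dict(ds.codebook)
    cb["age_group"] = survey.FactorSpec("age_group", tuple(present), present[-1])
    return dataclasses.replace(ds, codebook=cb)


def run_pipeline(cfg: PipelineConfig, graph: AdjacencyGraph | None = None) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = graph or (load_graph(cfg.graph) if cfg.graph else default_drc_graph())

    if cfg.simulate:
        sim_cfg = default_survey_config(n=cfg.n_records, seed=cfg.seed)
        ds_raw, truth = generate(sim_cfg, g)
        survey.write_records(ds_raw, out / "records.csv")
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps({
            "beta0": truth.beta0, "beta": truth.beta,
            "f_age": list(truth.f_age), "s": truth.s, "u": truth.u,
        }, indent=1))
    else:
        ds_raw = read_records(cfg.records, survey.default_codebook(tuple(g.nodes)))
    n_raw = ds_raw.n
    ds = add_age_group(filter_complete(ds_raw))
    log.info("records: %d read, %d complete", n_raw, ds.n)

    manifest: dict = {
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "n_raw": n_raw,
        "n_complete": ds.n,
        "populations": {},
        "outputs": {},
    }

    for pop in cfg.populations:
        pds = _restrict_age_group(_population(ds, pop))
        pop_dir = out / pop
        pop_dir.mkdir(exist_ok=True)
        stage_t = time.time()

        # descriptives
        desc = []
        for f in DESCRIPTIVE_FACTORS:
            if len(pds.codebook[f].levels) < 2:
                continue
            t = survey.crosstab_percent(pds, f)
            t.insert(0, "factor", f)
            desc.append(t)
        pd.concat(desc, ignore_index=True).to_csv(pop_dir / "descriptives.csv", index=False)

        # classical: unadjusted (one single-factor fit per factor) + adjusted
        terms: list[str] = []
        if "classical" in cfg.stages:
            uni = []
            for f in DESCRIPTIVE_FACTORS:
                try:
                    dm = build_design(pds, [f], g)
                    t = classical.or_table(classical.fit_logistic_irls(dm), pds.codebook)
                    t.insert(0, "factor", f)
                    uni.append(t)
                except (classical.SeparationError, classical.ConvergenceError) as e:
                    log.warning("univariate fit for %s failed: %s", f, e)
            pd.concat(uni, ignore_index=True).to_csv(pop_dir / "univariate.csv", index=False)

            terms = [t for t in cfg.adjusted_terms[pop] if len(pds.codebook[t].levels) >= 2]
            dm_adj = build_design(pds, terms, g)
            classical.or_table(classical.fit_logistic_irls(dm_adj), pds.codebook).to_csv(
                pop_dir / "adjusted.csv", index=False
            )
            log.info("[%s] classical stage done in %.1fs", pop, time.time() - stage_t)

        # Bayesian geo-additive fit
        stage_t = time.time()
        rhat_box = [None]
        if "bayes" in cfg.stages:
            try:
                rhat_box[0] = _bayes_stage(cfg, pds, g, pop, pop_dir)
            except Exception as e:
                for f in pop_dir.glob("*.csv"):
                    manifest["outputs"][f"{pop}/{f.name}"] = _sha256(f)
                manifest["failed_stage"] = f"{pop}/bayesian"
                manifest["failure"] = str(e)
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
                raise RuntimeError(f"stage {pop}/bayesian failed: {e}") from e
        manifest["populations"][pop] = {"n": pds.n, "adjusted_terms": list(terms), "rhat": rhat_box[0]}
        for f in pop_dir.glob("*.csv"):
            manifest["outputs"][f"{pop}/{f.name}"] = _sha256(f)
        log.info("[%s] Bayesian stage done in %.1fs; Rhat=%s", pop, time.time() - stage_t, rhat_box[0])

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _bayes_stage(cfg: PipelineConfig, pds: Dataset, g: AdjacencyGraph, pop: str, pop_dir: Path) -> dict:
    ages = pds.df["age_years"].astype(float)
    n_basis = cfg.n_basis_all if pop == "all" else cfg.n_basis_young
    basis = SplineBasis.for_range(float(ages.min()), float(ages.max()), n_basis=n_basis)
    dm_b = build_design(pds, list(BAYES_FIXED_TERMS), g)
    spec = ModelSpec(smooth=basis, spatial=g, unstructured=cfg.unstructured)
    pop_offset = {"all": 0, "young": 1}.get(pop, 2)
    mcfg = MCMCConfig(cfg.n_iter, cfg.burn_in, cfg.thin, seed=cfg.seed * 8 + pop_offset, chains=cfg.chains)
    draws = run_mcmc(dm_b, spec, mcfg)
    summarize.fixed_effect_table(draws, level=max(cfg.report_levels)).to_csv(
        pop_dir / "bayes_fixed.csv", index=False
    )
    summarize.make_map_table(draws, g, level=min(cfg.report_levels), total=True).to_csv(
        pop_dir / "bayes_spatial_maptable.csv", index=False
    )
    summarize.age_effect_grid(draws, level=min(cfg.report_levels)).to_csv(
        pop_dir / "age_effect.csv", index=False
    )
    return draws.rhat_summary() if cfg.chains >= 2 else {}


def compare_tables(
    produced: pd.DataFrame,
    reference: pd.DataFrame,
    tolerance: float,
    keys: tuple[str, ...] = ("term", "level"),
    value_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Key-aligned per-cell diff of two report tables.

    Rows are matched on ``keys`` (order-insensitive); numeric columns are
    compared with absolute and relative differences and a pass/fail flag at
    ``tolerance`` (absolute).  Mismatched key sets raise.
    """
    keys = [k for k in keys if k in produced.columns]
    a = produced.set_index(list(keys)).sort_index()
    b = reference.set_index(list(keys)).sort_index()
    if set(a.index) != set(b.index):
        raise ValueError("tables have different row keys")
    b = b.loc[a.index]
    if value_cols is None:
        value_cols = tuple(c for c in a.columns if pd.api.types.is_numeric_dtype(a[c]) and c in b.columns)
    rows = []
    for col in value_cols:
        diff = a[col].astype(float) - b[col].astype(float)
        denom = b[col].astype(float).abs().replace(0, np.nan)
        both_nan = a[col].isna() & b[col].isna()
        ok = (diff.abs() <= tolerance) | both_nan
        for idx in a.index:
            rows.append(
                {
                    "key": idx,
                    "column": col,
                    "abs_diff": float(diff.loc[idx]) if not both_nan.loc[idx] else 0.0,
                    "rel_diff": float((diff / denom).loc[idx]) if not both_nan.loc[idx] else 0.0,
                    "pass": bool(ok.loc[idx]),
                }
            )
    return pd.DataFrame(rows)
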