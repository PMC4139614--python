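"""Pólya-Gamma Gibbs sampler for the geo-additive logistic model.

Model for observation i with covariate row x_i, age a_i and region r_i:

    y_i ~ Bernoulli(sigmoid(eta_i)),
    eta_i = x_i' beta + B(a_i)' gamma + s_{r_i} + u_{r_i},

with priors beta ~ N(0, c I) (c large), gamma ~ N(0, tau2_f K^-) for the RW2
penalty K (intrinsic), s ~ ICAR(tau2_s) on the region graph, u ~ iid
N(0, sigma2_u), and conjugate inverse-gamma hyperpriors on the variances.
A diffuse ridge (precision 1/c) is added to every coefficient because the
intrinsic priors leave exact flat directions (e.g. a constant moved between
gamma and s); the per-iteration recentering then fixes the level allocation.

Augmenting each observation with omega_i ~ PG(1, eta_i) makes the full
conditional of the stacked coefficient vector exactly Gaussian, so the Gibbs
cycle needs no tuning:

    1. omega_i | eta_i  ~ PG(1, eta_i)
    2. theta | omega    ~ N(Lambda^-1 Z'(y - 1/2), Lambda^-1),
       Lambda = Z' diag(omega) Z + blockdiag(prior precisions)
    3. re-center s and the smooth's fitted values, absorbing the constants
       into the intercept (identifiability of the intrinsic terms)
    4. variances from their inverse-gamma full conditionals.

The sampler is exact (the invariant law is the stated posterior); the only
approximations downstream are Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from ._polyagamma import pg_array
from .graph import AdjacencyGraph, icar_precision, is_connected
from .splines import SplineBasis
from .survey import DesignMatrix

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "GibbsKernel",
    "run_mcmc",
    "effective_sample_size",
    "gelman_rubin",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the structured additive predictor, and their priors.

    ``tau2_f_fixed`` / ``tau2_s_fixed`` / ``sigma2_u_fixed`` pin a variance
    instead of sampling it; ``recenter=False`` disables the identifiability
    recentering (both are diagnostic hooks, e.g. shrinkage-limit checks and
    prior-reproduction tests on proper-prior configurations).
    """

    smooth: SplineBasis | None = None
    spatial: AdjacencyGraph | None = None
    unstructured: bool = True
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    fixed_prior_var: float = 1e6
    tau2_f_fixed: float | None = None
    tau2_s_fixed: float | None = None
    sigma2_u_fixed: float | None = None
    recenter: bool = True

    def __post_init__(self) -> None:
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0
    chains: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorDraws:
    """Stored post-burn-in draws, shaped (chains, draws, dim)."""

    beta: np.ndarray
    beta_columns: tuple[str, ...]
    gamma: np.ndarray | None
    s: np.ndarray | None
    u: np.ndarray | None
    tau2_f: np.ndarray | None
    tau2_s: np.ndarray | None
    sigma2_u: np.ndarray | None
    node_order: tuple[str, ...] | None
    basis: SplineBasis | None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def pooled(self, arr: np.ndarray) -> np.ndarray:
        """Collapse the chain axis."""
        return arr.reshape(-1, *arr.shape[2:])

    def total_spatial(self) -> np.ndarray:
        """Structured + unstructured region effect (chains, draws, regions)."""
        if self.s is None:
            raise ValueError("no spatial term in this fit")
        return self.s + self.u if self.u is not None else self.s

    def save(self, path: str, meta: dict | None = None) -> None:
        """Persist draws as one flat CSV plus a JSON sidecar (``path`` +
        ``.csv`` / ``.json``); the sidecar records shapes, node order and a
        content hash of the table."""
        import hashlib
        import json
        from pathlib import Path

        import pandas as pd

        cols: dict[str, np.ndarray] = {}
        n_c, n_d = self.beta.shape[:2]
        cols["chain"] = np.repeat(np.arange(n_c), n_d)
        cols["draw"] = np.tile(np.arange(n_d), n_c)
        for name, arr in (("beta", self.beta), ("gamma", self.gamma), ("s", self.s), ("u", self.u)):
            if arr is None:
                continue
            flat = self.pooled(arr)
            labels = (
                self.beta_columns if name == "beta"
                else self.node_order if name in ("s", "u")
                else [f"gamma{j}" for j in range(arr.shape[2])]
            )
            for j, lab in enumerate(labels):
                cols[f"{name}:{lab}"] = flat[:, j]
        for name, arr in (("tau2_f", self.tau2_f), ("tau2_s", self.tau2_s), ("sigma2_u", self.sigma2_u)):
            if arr is not None:
                cols[name] = arr.reshape(-1)
        csv_path = Path(str(path) + ".csv")
        pd.DataFrame(cols).to_csv(csv_path, index=False)
        sidecar = {
            "chains": n_c,
            "draws_per_chain": n_d,
            "beta_columns": list(self.beta_columns),
            "node_order": list(self.node_order) if self.node_order else None,
            "n_basis": self.gamma.shape[2] if self.gamma is not None else None,
            "sha256": hashlib.sha256(csv_path.read_bytes()).hexdigest(),
            **(meta or {}),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    def rhat_summary(self) -> dict[str, float]:
        """Max split-Rhat per coefficient block (requires >= 2 chains)."""
        out = {}
        for name, arr in (("beta", self.beta), ("gamma", self.gamma), ("s", self.s), ("u", self.u)):
            if arr is None:
                continue
            out[name] = max(
                gelman_rubin([arr[c, :, j] for c in range(arr.shape[0])])
                for j in range(arr.shape[2])
            )
        return out


class GibbsKernel:
    """One full scan of the PG-augmented Gibbs cycle, holding its own state.

    Exposed (rather than buried in :func:`run_mcmc`) so the update can be
    validated directly, e.g. by successive-conditional simulation against
    the prior.
    """

    def __init__(self, dm: DesignMatrix, spec: ModelSpec):
        self.spec = spec
        n, p = dm.X.shape
        self.p = p
        blocks: list[np.ndarray] = [dm.X]
        self.slices: dict[str, slice] = {"beta": slice(0, p)}
        self.K = self.Q = None
        self.m = self.nr = 0

        if spec.smooth is not None:
            self.B = spec.smooth.design(dm.age)
            self.m = self.B.shape[1]
            self.K = spec.smooth.penalty()
            self.slices["gamma"] = slice(p, p + self.m)
            blocks.append(self.B)
        if spec.spatial is not None:
            if not is_connected(spec.spatial):
                raise ValueError("spatial term requires a connected graph")
            if tuple(spec.spatial.nodes) != tuple(dm.node_order):
                raise ValueError("design matrix node order does not match the graph")
            self.nr = spec.spatial.n_nodes
            if self.nr < 2:
                raise ValueError("spatial term needs at least two regions")
            self.Q = icar_precision(spec.spatial).Q
            E = np.zeros((n, self.nr))
            E[np.arange(n), dm.province_index] = 1.0
            off = p + self.m
            self.slices["s"] = slice(off, off + self.nr)
            blocks.append(E)
            if spec.unstructured:
                self.slices["u"] = slice(off + self.nr, off + 2 * self.nr)
                blocks.append(E)
        self.Z = np.ascontiguousarray(np.column_stack(blocks))
        self.d = self.Z.shape[1]
        self.has_smooth = spec.smooth is not None
        self.has_spatial = spec.spatial is not None
        self.has_u = self.has_spatial and spec.unstructured
        self.rank_K = self.m - 2 if self.has_smooth else 0
        self.set_response(dm.y)
        self.reset()

    def set_response(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float)
        self.Ztk = self.Z.T @ (self.y - 0.5)

    def reset(self) -> None:
        spec = self.spec
        self.theta = np.zeros(self.d)
        self.tau2_f = spec.tau2_f_fixed if spec.tau2_f_fixed is not None else 0.1
        self.tau2_s = spec.tau2_s_fixed if spec.tau2_s_fixed is not None else 0.1
        self.sigma2_u = spec.sigma2_u_fixed if spec.sigma2_u_fixed is not None else 0.1

    def prior_precision(self) -> np.ndarray:
        spec = self.spec
        prec = np.eye(self.d) / spec.fixed_prior_var
        if self.has_smooth:
            sl = self.slices["gamma"]
            prec[sl, sl] += self.K / self.tau2_f
        if self.has_spatial:
            sl = self.slices["s"]
            prec[sl, sl] += self.Q / self.tau2_s
        if self.has_u:
            sl = self.slices["u"]
            prec[sl.start + np.arange(self.nr), sl.start + np.arange(self.nr)] += 1.0 / self.sigma2_u
        return prec

    def eta(self) -> np.ndarray:
        return self.Z @ self.theta

    def step(self, rng: np.random.Generator, iteration: int = 0) -> None:
        spec = self.spec
        eta = self.eta()
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError(f"non-finite linear predictor at iteration {iteration}")
        omega = np.maximum(pg_array(eta, int(rng.integers(0, 2**31 - 1))), 1e-12)

        Lam = (self.Z * omega[:, None]).T @ self.Z + self.prior_precision()
        cF, lower = sla.cho_factor(Lam, lower=True, check_finite=False)
        mu = sla.cho_solve((cF, lower), self.Ztk, check_finite=False)
        xi = rng.standard_normal(self.d)
        self.theta = mu + sla.solve_triangular(cF, xi, lower=lower, trans="T", check_finite=False)

        if spec.recenter:
            if self.has_spatial:
                sl = self.slices["s"]
                shift = self.theta[sl].mean()
                self.theta[sl] -= shift
                self.theta[0] += shift
            if self.has_smooth:
                sl = self.slices["gamma"]
                # rows of B sum to 1, so shifting every gamma by a constant
                # shifts the fitted smooth by exactly that constant
                offset = float(np.mean(self.B @ self.theta[sl]))
                self.theta[sl] -= offset
                self.theta[0] += offset

        if self.has_smooth and spec.tau2_f_fixed is None:
            g = self.theta[self.slices["gamma"]]
            self.tau2_f = _inv_gamma(rng, spec.hyper_a + self.rank_K / 2.0,
                                     spec.hyper_b + 0.5 * g @ self.K @ g)
        if self.has_spatial and spec.tau2_s_fixed is None:
            s = self.theta[self.slices["s"]]
            self.tau2_s = _inv_gamma(rng, spec.hyper_a + (self.nr - 1) / 2.0,
                                     spec.hyper_b + 0.5 * s @ self.Q @ s)
        if self.has_u and spec.sigma2_u_fixed is None:
            u = self.theta[self.slices["u"]]
            self.sigma2_u = _inv_gamma(rng, spec.hyper_a + self.nr / 2.0,
                                       spec.hyper_b + 0.5 * u @ u)


def run_mcmc(dm: DesignMatrix, spec: ModelSpec, cfg: MCMCConfig) -> PosteriorDraws:
    """Run the PG-augmented Gibbs sampler; reproducible from ``cfg.seed``."""
    kernel = GibbsKernel(dm, spec)
    n_draws = cfg.n_draws
    p, m, nr = kernel.p, kernel.m, kernel.nr

    beta_st = np.empty((cfg.chains, n_draws, p))
    gamma_st = np.empty((cfg.chains, n_draws, m)) if kernel.has_smooth else None
    s_st = np.empty((cfg.chains, n_draws, nr)) if kernel.has_spatial else None
    u_st = np.empty((cfg.chains, n_draws, nr)) if kernel.has_u else None
    t2f_st = np.empty((cfg.chains, n_draws)) if kernel.has_smooth else None
    t2s_st = np.empty((cfg.chains, n_draws)) if kernel.has_spatial else None
    s2u_st = np.empty((cfg.chains, n_draws)) if kernel.has_u else None

    master = np.random.SeedSequence(cfg.seed)
    for chain, ss in enumerate(master.spawn(cfg.chains)):
        rng = np.random.default_rng(ss)
        kernel.reset()
        k = 0
        for it in range(cfg.n_iter):
            kernel.step(rng, it)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                beta_st[chain, k] = kernel.theta[kernel.slices["beta"]]
                if kernel.has_smooth:
                    gamma_st[chain, k] = kernel.theta[kernel.slices["gamma"]]
                    t2f_st[chain, k] = kernel.tau2_f
                if kernel.has_spatial:
                    s_st[chain, k] = kernel.theta[kernel.slices["s"]]
                    t2s_st[chain, k] = kernel.tau2_s
                if kernel.has_u:
                    u_st[chain, k] = kernel.theta[kernel.slices["u"]]
                    s2u_st[chain, k] = kernel.sigma2_u
                k += 1
        log.info("chain %d finished: %d stored draws", chain, k)

    return PosteriorDraws(
        beta=beta_st,
        beta_columns=dm.columns,
        gamma=gamma_st,
        s=s_st,
        u=u_st,
        tau2_f=t2f_st,
        tau2_s=t2s_st,
        sigma2_u=s2u_st,
        node_order=tuple(dm.node_order) if kernel.has_spatial else None,
        basis=spec.smooth,
    )


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return float(max(scale, 1e-300) / rng.gamma(shape))


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence on the autocorrelation sum."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        raise ValueError("constant chain: ESS undefined")
    # autocovariances via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum paired autocorrelations while the pair sums stay positive
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        total += pair
        t += 2
    ess = n / (1.0 + 2.0 * total)
    return float(min(max(ess, 1e-12), n))


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Split-Rhat potential scale reduction factor (>= 2 chains)."""
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    halves = []
    for c in chains:
        c = np.asarray(c, dtype=float)
        h = len(c) // 2
        halves.extend([c[:h], c[h : 2 * h]])
    n = min(len(h) for h in halves)
    arr = np.stack([h[:n] for h in halves])
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return float("inf") if b > 0 else 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))
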