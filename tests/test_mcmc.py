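import numpy as np
import pytest
from scipy import stats

import geobirth as gb
from geobirth.mcmc import GibbsKernel, MCMCConfig, ModelSpec, effective_sample_size, gelman_rubin
from geobirth.splines import SplineBasis
from geobirth.survey import DesignMatrix, build_design

from conftest import path_graph


def _intercept_design(y, province=None, nodes=("A",)):
    n = len(y)
    return DesignMatrix(
        y=np.asarray(y, dtype=float),
        X=np.ones((n, 1)),
        columns=("intercept",),
        term_index={"intercept": (0,)},
        age=np.full(n, 30.0),
        province_index=np.zeros(n, dtype=np.int64) if province is None else province,
        node_order=tuple(nodes),
    )


def test_intercept_only_posterior_concentrates():
    rng = np.random.default_rng(0)
    y = (rng.random(5000) < 0.3).astype(float)
    dm = _intercept_design(y)
    draws = gb.run_mcmc(dm, ModelSpec(smooth=None, spatial=None, unstructured=False),
                        MCMCConfig(1500, 300, 2, seed=1, chains=1))
    chain = draws.beta[0, :, 0]
    target = np.log(0.3 / 0.7)
    assert chain.mean() == pytest.approx(target, abs=3 * chain.std() + 0.02)


def test_spatial_shrinkage_limit():
    """With the spatial variance pinned near zero, s collapses to zero."""
    g = path_graph(("A", "B", "C"))
    rng = np.random.default_rng(2)
    prov = rng.integers(0, 3, 600).astype(np.int64)
    y = (rng.random(600) < 0.4).astype(float)
    dm = _intercept_design(y, province=prov, nodes=g.nodes)
    spec = ModelSpec(smooth=None, spatial=g, unstructured=False, tau2_s_fixed=1e-6)
    draws = gb.run_mcmc(dm, spec, MCMCConfig(400, 100, 1, seed=3, chains=1))
    assert np.abs(draws.s).max() < 0.01


def test_stored_spatial_draws_are_centered(preset_dataset, drc_graph):
    ds, _ = preset_dataset
    sub = ds.with_df(ds.df.head(1200))
    dm = build_design(sub, ["residence"], drc_graph)
    spec = ModelSpec(smooth=None, spatial=drc_graph, unstructured=True)
    draws = gb.run_mcmc(dm, spec, MCMCConfig(300, 100, 2, seed=4, chains=1))
    assert np.abs(draws.s.sum(axis=2)).max() < 1e-10
    assert (draws.tau2_s > 0).all() and (draws.sigma2_u > 0).all()


def test_fixed_effects_match_irls_without_smooth_or_spatial(drc_graph):
    """Bernstein-von-Mises sanity: flat-prior Bayes ~ maximum likelihood."""
    cfg = gb.default_survey_config(n=5000, seed=31)
    ds, _ = gb.generate(cfg, drc_graph)
    dm = build_design(ds, ["residence", "education"], drc_graph)
    irls = gb.fit_logistic_irls(dm)
    draws = gb.run_mcmc(dm, ModelSpec(smooth=None, spatial=None, unstructured=False),
                        MCMCConfig(2000, 500, 2, seed=5, chains=1))
    post_mean = draws.pooled(draws.beta).mean(axis=0)
    post_sd = draws.pooled(draws.beta).std(axis=0)
    combined = np.sqrt(post_sd**2 + irls.se() ** 2)
    assert np.all(np.abs(post_mean - irls.coefficients) < 3 * combined)


def test_gibbs_kernel_preserves_proper_prior():
    """Successive-conditional simulation: alternating theta-update and data
    regeneration must leave the (proper) prior marginals invariant."""
    g = path_graph(("A", "B", "C"))
    rng = np.random.default_rng(42)
    prov = rng.integers(0, 3, 40).astype(np.int64)
    dm = _intercept_design(np.zeros(40), province=prov, nodes=g.nodes)
    spec = ModelSpec(
        smooth=None, spatial=g, unstructured=False,
        fixed_prior_var=1.0, tau2_s_fixed=0.5, recenter=False,
    )
    kernel = GibbsKernel(dm, spec)
    P = kernel.prior_precision()
    prior_cov = np.linalg.inv(P)

    # start from a draw of the proper prior
    L = np.linalg.cholesky(prior_cov)
    kernel.theta = L @ rng.standard_normal(kernel.d)
    kept = []
    for scan in range(4500):
        eta = kernel.eta()
        y = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)
        kernel.set_response(y)
        kernel.step(rng)
        if scan % 3 == 0:
            kept.append(kernel.theta.copy())
    kept = np.array(kept)
    for j in range(kernel.d):
        z = kept[:, j] / np.sqrt(prior_cov[j, j])
        assert stats.kstest(z, "norm").pvalue > 0.01, f"coordinate {j}"


def test_label_equivariance_of_spatial_posteriors(drc_graph):
    """Swapping two province labels in data and graph permutes the posterior
    spatial means (statistically, up to MC error)."""
    cfg = gb.default_survey_config(n=2500, seed=17)
    ds, _ = gb.generate(cfg, drc_graph)
    mcfg = MCMCConfig(2500, 500, 4, seed=9, chains=1)

    dm = build_design(ds, ["residence"], drc_graph)
    d1 = gb.run_mcmc(dm, ModelSpec(smooth=None, spatial=drc_graph, unstructured=False), mcfg)

    swapped_nodes = list(drc_graph.nodes)
    i, j = swapped_nodes.index("KIN"), swapped_nodes.index("SKV")
    swapped_nodes[i], swapped_nodes[j] = swapped_nodes[j], swapped_nodes[i]
    g2 = gb.AdjacencyGraph.from_edges(swapped_nodes, drc_graph.edges)
    dm2 = build_design(ds, ["residence"], g2)
    d2 = gb.run_mcmc(dm2, ModelSpec(smooth=None, spatial=g2, unstructured=False), mcfg)

    m1 = dict(zip(d1.node_order, d1.pooled(d1.s).mean(axis=0)))
    m2 = dict(zip(d2.node_order, d2.pooled(d2.s).mean(axis=0)))
    for prov in drc_graph.nodes:
        assert m1[prov] == pytest.approx(m2[prov], abs=0.08)


def test_disconnected_graph_rejected():
    g = gb.AdjacencyGraph.from_edges(["A", "B", "C"], [("A", "B")])
    dm = _intercept_design(np.zeros(10), province=np.zeros(10, dtype=np.int64), nodes=g.nodes)
    with pytest.raises(ValueError, match="connected"):
        gb.run_mcmc(dm, ModelSpec(smooth=None, spatial=g), MCMCConfig(20, 5, 1))


def test_ess_white_noise_and_ar1():
    rng = np.random.default_rng(6)
    white = rng.standard_normal(1000)
    assert effective_sample_size(white) == pytest.approx(1000, rel=0.2)

    rho = 0.9
    n = 20000
    ar = np.empty(n)
    ar[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for t in range(1, n):
        ar[t] = rho * ar[t - 1] + eps[t]
    expected = n * (1 - rho) / (1 + rho)
    assert effective_sample_size(ar) == pytest.approx(expected, rel=0.3)

    doubled = np.repeat(rng.standard_normal(300), 2)
    assert effective_sample_size(doubled) < 600
    with pytest.raises(ValueError):
        effective_sample_size(np.ones(100))


def test_ess_agrees_with_arviz_on_mcmc_output():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(12)
    n = 4000
    ar = np.empty(n)
    ar[0] = 0.0
    for t in range(1, n):
        ar[t] = 0.6 * ar[t - 1] + rng.standard_normal()
    ours = effective_sample_size(ar)
    ref = float(az.ess(ar[None, :], method="bulk"))
    assert ours == pytest.approx(ref, rel=0.35)


def test_gelman_rubin_cases():
    rng = np.random.default_rng(7)
    same = [rng.standard_normal(2000) for _ in range(3)]
    assert gelman_rubin(same) < 1.05
    apart = [rng.standard_normal(500), rng.standard_normal(500) + 10]
    assert gelman_rubin(apart) > 1.5
    a, b = rng.standard_normal(800), rng.standard_normal(800)
    r0 = gelman_rubin([a, b])
    r1 = gelman_rubin([5 * a - 3, 5 * b - 3])
    assert r0 == pytest.approx(r1, rel=1e-10)
    with pytest.raises(ValueError):
        gelman_rubin([a])


def test_posterior_draws_round_trip_to_csv(tmp_path, drc_graph, preset_dataset):
    import json
    import pandas as pd

    ds, _ = preset_dataset
    sub = ds.with_df(ds.df.head(400))
    dm = build_design(sub, ["residence"], drc_graph)
    spec = ModelSpec(smooth=None, spatial=drc_graph, unstructured=False)
    draws = gb.run_mcmc(dm, spec, MCMCConfig(120, 40, 2, seed=8, chains=2))
    draws.save(tmp_path / "draws", meta={"seed": 8})
    table = pd.read_csv(tmp_path / "draws.csv")
    assert len(table) == 2 * draws.beta.shape[1]
    np.testing.assert_allclose(table["s:KIN"].to_numpy(), draws.pooled(draws.s)[:, 0])
    sidecar = json.loads((tmp_path / "draws.json").read_text())
    assert sidecar["chains"] == 2 and sidecar["seed"] == 8
    assert sidecar["node_order"][0] == "KIN"
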