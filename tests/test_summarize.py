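import numpy as np
import pytest

import geobirth as gb
from geobirth.mcmc import PosteriorDraws
from geobirth.splines import SplineBasis
from geobirth.summarize import (
    age_effect_grid,
    classify_significance,
    fixed_effect_table,
    make_map_table,
    summarize_effect,
)


def _fake_draws(s=None, u=None, gamma=None, basis=None, nodes=None):
    n_draws = s.shape[0] if s is not None else (gamma.shape[0] if gamma is not None else 100)
    return PosteriorDraws(
        beta=np.zeros((1, n_draws, 1)),
        beta_columns=("intercept",),
        gamma=gamma[None] if gamma is not None else None,
        s=s[None] if s is not None else None,
        u=u[None] if u is not None else None,
        tau2_f=None, tau2_s=None, sigma2_u=None,
        node_order=nodes,
        basis=basis,
    )


def test_constant_chain_gives_unit_por():
    summ = summarize_effect(np.zeros(500))
    assert summ.por == 1.0
    assert summ.credible_region(0.95) == (1.0, 1.0)
    with pytest.raises(ValueError):
        summarize_effect(np.array([]))


def test_normal_quantiles_oracle():
    rng = np.random.default_rng(1)
    summ = summarize_effect(rng.standard_normal(100_000))
    lo, hi = summ._log_cr(0.95)
    assert lo == pytest.approx(-1.96, abs=0.02)
    assert hi == pytest.approx(1.96, abs=0.02)
    lo80, hi80 = summ._log_cr(0.80)
    assert lo80 == pytest.approx(-1.2816, abs=0.02)


def test_shift_equivariance_exact():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(1000)
    a = summarize_effect(x)
    b = summarize_effect(x + 0.7)
    assert b.mean == pytest.approx(a.mean + 0.7, abs=1e-12)
    for q in a.quantiles:
        assert b.quantiles[q] == pytest.approx(a.quantiles[q] + 0.7, abs=1e-12)


def test_classification_rules():
    rng = np.random.default_rng(3)
    pos = summarize_effect(np.abs(rng.standard_normal(1000)) + 0.01)
    assert classify_significance(pos, 0.95) == 1
    sym = summarize_effect(rng.standard_normal(1000))
    assert classify_significance(sym, 0.80) == 0
    shifted = summarize_effect(rng.normal(0.5, 0.1, 5000))
    assert classify_significance(shifted, 0.80) == 1
    assert classify_significance(shifted, 0.95) == 1
    with pytest.raises(ValueError):
        classify_significance(sym, 0.5)


def test_significance_monotone_in_level():
    """95%-significance implies 80%-significance (CR nesting)."""
    rng = np.random.default_rng(4)
    for shift in np.linspace(-0.3, 0.3, 13):
        summ = summarize_effect(rng.normal(shift, 0.15, 2000))
        if classify_significance(summ, 0.95) != 0:
            assert classify_significance(summ, 0.80) == classify_significance(summ, 0.95)


def test_map_table_null_effects(drc_graph):
    s = np.zeros((200, 11))
    draws = _fake_draws(s=s, nodes=drc_graph.nodes)
    t = make_map_table(draws, drc_graph, level=0.80, total=True)
    assert (t["POR"] == 1.0).all()
    assert (t["class"] == 0).all()
    assert list(t["province"]) == list(drc_graph.nodes)


def test_map_table_combines_structured_and_unstructured(drc_graph):
    rng = np.random.default_rng(5)
    s = rng.normal(0, 0.01, (4000, 11))
    u = np.full((4000, 11), 0.0)
    u[:, 2] = 0.8  # unstructured excess in the third province
    t_total = make_map_table(_fake_draws(s=s, u=u, nodes=drc_graph.nodes), level=0.80, total=True)
    t_struct = make_map_table(_fake_draws(s=s, u=u, nodes=drc_graph.nodes), level=0.80, total=False)
    assert t_total.loc[2, "class"] == 1
    assert t_struct.loc[2, "class"] == 0
    with pytest.raises(ValueError):
        make_map_table(_fake_draws(gamma=np.zeros((10, 3))), level=0.80)


def test_age_effect_grid_centering_and_band():
    basis = SplineBasis.for_range(15, 49, n_basis=10)
    rng = np.random.default_rng(6)
    gamma = rng.normal(0, 0.3, (500, 10))
    # center each draw's fitted values over the grid, mimicking the sampler
    grid = np.arange(15, 50, dtype=float)
    Bg = basis.design(grid)
    gamma -= (Bg @ gamma.T).mean(axis=0)[:, None]
    draws = _fake_draws(gamma=gamma, basis=basis)
    t = age_effect_grid(draws, grid=grid)
    assert abs(t["mean"].mean()) < 1e-10
    assert (t["cr_high"] > t["cr_low"]).all()
    with pytest.raises(ValueError):
        age_effect_grid(draws, grid=np.array([10.0]))


def test_fixed_effect_table_shapes():
    rng = np.random.default_rng(7)
    draws = PosteriorDraws(
        beta=rng.normal(0.4, 0.05, (2, 300, 2)),
        beta_columns=("intercept", "residence[rural]"),
        gamma=None, s=None, u=None, tau2_f=None, tau2_s=None, sigma2_u=None,
        node_order=None, basis=None,
    )
    t = fixed_effect_table(draws)
    assert list(t["term"]) == ["intercept", "residence[rural]"]
    assert (t["POR"] > 1).all() and (t["class"] == 1).all()
    assert (t["POR_mean_exp"] >= t["POR"]).all()  # Jensen


def test_join_map_geojson_attaches_properties(drc_graph):
    s = np.zeros((50, 11))
    s[:, 0] = -0.5
    t = make_map_table(_fake_draws(s=s, nodes=drc_graph.nodes), level=0.80)
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"province": "KIN"}, "geometry": None},
            {"type": "Feature", "properties": {"province": "ZZZ"}, "geometry": None},
        ],
    }
    out = gb.summarize.join_map_geojson(t, gj)
    assert out["features"][0]["properties"]["class"] == -1
    assert out["features"][0]["properties"]["POR"] < 1
    assert "class" not in out["features"][1]["properties"]
    assert "class" not in gj["features"][0]["properties"]  # input untouched
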