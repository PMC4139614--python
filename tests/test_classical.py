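import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import geobirth as gb
from geobirth.classical import (
    SeparationError,
    chi_square_independence,
    fit_logistic_irls,
    mann_whitney_u,
    or_from_counts,
    or_from_props,
    or_table,
)
from geobirth.survey import build_design


def _expand_2x2(a, b, c, d):
    """Rows of (y, exposed) for a 2x2 table."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    X = np.column_stack([np.ones_like(x), x])
    return y, X


def test_or_from_props_identity_and_reciprocal():
    assert or_from_props(0.3, 0.3) == pytest.approx(1.0)
    assert or_from_props(0.4, 0.2) * or_from_props(0.2, 0.4) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        or_from_props(0.0, 0.5)


def test_or_from_counts_exact_and_symmetric():
    orr, lo, hi = or_from_counts(10, 10, 5, 15)
    assert orr == pytest.approx(3.0)
    orr1, lo1, hi1 = or_from_counts(7, 7, 7, 7)
    assert orr1 == pytest.approx(1.0)
    assert np.log(hi1) == pytest.approx(-np.log(lo1))
    with pytest.raises(ValueError):
        or_from_counts(0, 5, 5, 5)
    orr0, _, _ = or_from_counts(0, 5, 5, 5, continuity=True)
    assert 0 < orr0 < 1


def test_irls_intercept_only_closed_form():
    y = np.array([1.0] * 25 + [0.0] * 75)
    X = np.ones((100, 1))
    fit = fit_logistic_irls((y, X))
    assert fit.coefficients[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
    assert fit.converged


def test_irls_equals_closed_form_2x2():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a, b, c, d = rng.integers(3, 60, size=4)
        orr, lo, hi = or_from_counts(a, b, c, d)
        fit = fit_logistic_irls(_expand_2x2(a, b, c, d))
        assert np.exp(fit.coefficients[1]) == pytest.approx(orr, abs=1e-8)
        se = fit.se()[1]
        assert np.exp(fit.coefficients[1] - 1.959963984540054 * se) == pytest.approx(lo, rel=1e-6)


def test_irls_detects_separation():
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    x = np.array([-3, -2, -1, 1, 2, 3], dtype=float)
    X = np.column_stack([np.ones(6), x])
    with pytest.raises(SeparationError):
        fit_logistic_irls((y, X))


def test_irls_matches_statsmodels_oracle(preset_dataset):
    sm = pytest.importorskip("statsmodels.api")
    ds, _ = preset_dataset
    dm = build_design(ds, ["residence", "education", "wealth"])
    fit = fit_logistic_irls(dm)
    ref = sm.Logit(dm.y, dm.X).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se(), ref.bse, rtol=1e-4)


def test_or_recovery_on_synthetic_truth(drc_graph):
    cfg = gb.default_survey_config(n=50_000, seed=21)
    ds, truth = gb.generate(cfg, drc_graph)
    dm = build_design(ds, ["residence"])
    fit = fit_logistic_irls(dm)
    est = np.exp(fit.coefficients[1])
    assert est == pytest.approx(1.5, abs=0.1)


def test_or_table_reference_rows_and_ci_nesting(tiny_dataset, preset_dataset):
    ds, _ = preset_dataset
    dm = build_design(ds, ["education"])
    fit = fit_logistic_irls(dm)
    t95 = or_table(fit, ds.codebook, level=0.95).set_index("level")
    t80 = or_table(fit, ds.codebook, level=0.80).set_index("level")
    assert bool(t95.loc["secondary_plus", "reference"])
    assert t95.loc["secondary_plus", "OR"] == 1.0
    for lev in ("none", "primary"):
        assert t95.loc[lev, "ci_low"] <= t80.loc[lev, "ci_low"]
        assert t80.loc[lev, "ci_high"] <= t95.loc[lev, "ci_high"]
        assert t95.loc[lev, "ci_low"] <= t95.loc[lev, "OR"] <= t95.loc[lev, "ci_high"]


def test_chi_square_examples_and_permutation():
    x2, df, p = chi_square_independence([[10, 20], [10, 20]])
    assert x2 == pytest.approx(0.0) and p == pytest.approx(1.0)
    x2b, dfb, _ = chi_square_independence([[10, 20], [20, 10]])
    assert x2b == pytest.approx(20 / 3)
    assert dfb == 1
    x2c, _, _ = chi_square_independence([[20, 10], [10, 20]])
    assert x2c == pytest.approx(x2b)
    with pytest.raises(ValueError):
        chi_square_independence([[0, 0], [1, 2]])


def test_chi_square_matches_scipy():
    table = np.array([[12, 30, 8], [25, 14, 19]])
    x2, df, p = chi_square_independence(table)
    ref = stats.chi2_contingency(table, correction=False)
    assert x2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_mann_whitney_null_center_and_extreme():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    u, z, p = mann_whitney_u(x, x.copy())
    assert u == pytest.approx(len(x) ** 2 / 2)
    assert z == pytest.approx(0.0)
    u0, z0, _ = mann_whitney_u(np.array([1.0, 2.0]), np.array([5.0, 6.0, 7.0]))
    assert u0 == 0.0 and z0 < 0
    with pytest.raises(ValueError):
        mann_whitney_u(np.ones(3), np.ones(4))


def _exact_mw_p(x, y):
    """Two-sided p by enumeration of all assignments of pooled ranks."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * len(y) / 2
    stat = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += abs(u - mu) >= stat - 1e-12
        total += 1
    return count / total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mann_whitney_close_to_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 6)
    y = rng.normal(0.8, 1, 7)
    _, _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(_exact_mw_p(x, y), abs=0.03)


def test_mann_whitney_matches_scipy_with_ties():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 6, 40).astype(float)
    y = rng.integers(1, 7, 35).astype(float)
    u, z, p = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)
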