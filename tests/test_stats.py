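"""Exact nonparametric tests against brute-force enumeration, FDR procedures
against hand arithmetic and statsmodels, and the cohort derived quantities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from cfmeth.stats import (
    bh_adjust,
    bky_two_stage,
    combined_average,
    enzyme_correlation,
    fold_change,
    injury_contrast,
    mann_whitney,
    pre_post_contrast,
    spearman,
    wilcoxon_signed_rank,
)

# -- brute-force oracles (independent of the implementation) ----------------


def bf_signed_rank_p(d):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def bf_mann_whitney_p(a, b):
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        us.append(ranks[list(combo)].sum() - n_a * (n_a + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def bf_spearman_p(x, y):
    rx, ry = rankdata(x), rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    rhos = [
        np.corrcoef(rx, ry[list(p)])[0, 1]
        for p in itertools.permutations(range(len(y)))
    ]
    return np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)


# -- signed rank ------------------------------------------------------------


def test_signed_rank_all_positive_differences():
    res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    assert res.exact and res.statistic == 15
    assert res.p_value == pytest.approx(2 / 32)


def test_signed_rank_symmetric_pairs_give_p_one():
    res = wilcoxon_signed_rank([1.5, -1.5, 2.5, -2.5], [0, 0, 0, 0])
    assert res.p_value == 1.0


def test_signed_rank_self_comparison_undefined():
    res = wilcoxon_signed_rank([3, 1, 4], [3, 1, 4])
    assert res.n == 0 and math.isnan(res.p_value)


@given(
    st.lists(
        st.integers(-50, 50).filter(lambda v: v != 0), min_size=1, max_size=8, unique_by=abs
    )
)
def test_signed_rank_exact_matches_enumeration(d):
    res = wilcoxon_signed_rank(np.asarray(d, dtype=float))
    assert res.exact
    assert res.p_value == pytest.approx(bf_signed_rank_p(d))


def test_signed_rank_approximation_matches_scipy_for_large_n():
    from scipy.stats import wilcoxon as scipy_wilcoxon

    rng = np.random.default_rng(1)
    d = rng.normal(0.3, 1.0, size=40)
    res = wilcoxon_signed_rank(d)
    ref = scipy_wilcoxon(d, correction=False, mode="approx", alternative="two-sided")
    assert not res.exact
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# -- Mann-Whitney -----------------------------------------------------------


def test_mann_whitney_extreme_separation():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.exact and res.statistic == 0
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_single_observations():
    res = mann_whitney([1.0], [2.0])
    assert res.exact and res.p_value == 1.0


def test_mann_whitney_identical_groups_approximate_p_one():
    res = mann_whitney([1, 1, 2, 2, 3, 3, 4], [1, 1, 2, 2, 3, 3, 4])
    assert not res.exact  # ties force the approximation path
    assert res.p_value == 1.0


@given(
    st.lists(st.integers(0, 100), min_size=2, max_size=8, unique=True).flatmap(
        lambda pool: st.integers(1, len(pool) - 1).map(lambda k: (pool[:k], pool[k:]))
    )
)
def test_mann_whitney_exact_matches_enumeration(groups):
    a, b = groups
    res = mann_whitney(np.asarray(a, float), np.asarray(b, float))
    assert res.exact
    assert res.p_value == pytest.approx(bf_mann_whitney_p(a, b))


def test_mann_whitney_type_i_error_calibration():
    """Under the null, rejections at alpha=0.05 should occur ~5% of the time."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 10_000
    for _ in range(n_rep):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        if mann_whitney(a, b).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_rep <= 0.07


# -- Spearman ---------------------------------------------------------------


def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
    assert spearman([1, 2, 3], [6, 4, 2]).statistic == pytest.approx(-1.0)


def test_spearman_hand_computed_rho():
    res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert res.statistic == pytest.approx(0.8)
    assert res.exact


@given(
    st.lists(st.integers(0, 30), min_size=3, max_size=6),
    st.lists(st.integers(0, 30), min_size=6, max_size=6),
)
def test_spearman_exact_matches_permutation_enumeration(x, y):
    x = np.asarray(x + [5, 7, 9], dtype=float)[:6]
    y = np.asarray(y, dtype=float)
    if rankdata(x).std() == 0 or rankdata(y).std() == 0:
        return
    res = spearman(x, y)
    assert res.exact
    assert res.p_value == pytest.approx(bf_spearman_p(x, y))


def test_spearman_t_approximation_matches_scipy():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(3)
    x = rng.normal(size=25)
    y = x + rng.normal(size=25)
    res = spearman(x, y)
    ref = spearmanr(x, y)
    assert not res.exact
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# -- FDR procedures ---------------------------------------------------------


def test_bh_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_matches_statsmodels_and_is_monotone(pvals):
    q = bh_adjust(pvals)
    ref = multipletests(pvals, method="fdr_bh")[1]
    np.testing.assert_allclose(q, ref, atol=1e-12)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q[order] >= np.asarray(pvals)[order] - 1e-12)


def test_bky_worked_examples():
    assert bky_two_stage([1.0, 1.0, 1.0], 0.05).size == 0
    np.testing.assert_array_equal(bky_two_stage([0.0, 0.0], 0.05), [0, 1])
    np.testing.assert_array_equal(bky_two_stage([0.001, 0.2, 0.9], 0.05), [0])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=25), st.sampled_from([0.01, 0.05, 0.1]))
def test_bky_matches_statsmodels(pvals, alpha):
    rejected = np.zeros(len(pvals), dtype=bool)
    rejected[bky_two_stage(pvals, alpha)] = True
    ref = multipletests(pvals, alpha=alpha, method="fdr_tsbky")[0]
    np.testing.assert_array_equal(rejected, ref)


# -- derived longitudinal quantities ----------------------------------------


def test_fold_change():
    assert fold_change(0.02, 0.10) == pytest.approx(5.0)
    assert fold_change(0.3, 0.3) == 1.0
    assert math.isnan(fold_change(0.0, 0.5))
    with pytest.raises(ValueError):
        fold_change(-1.0, 0.5)


def test_combined_average():
    assert combined_average(0.10, 0.06) == pytest.approx(0.08)
    assert combined_average(0.10, float("nan")) == 0.10
    assert math.isnan(combined_average(float("nan"), float("nan")))


def _toy_cohort():
    rows = []
    for p, (pre, post, pod7, pod30, outcome) in enumerate(
        [
            (0.02, 0.22, 0.12, 0.10, "hepatocellular"),
            (0.03, 0.25, 0.15, 0.14, "mixed"),
            (0.02, 0.19, 0.14, 0.12, "biliary"),
            (0.02, 0.23, 0.03, 0.02, "no_injury"),
            (0.03, 0.21, 0.04, 0.03, "no_injury"),
            (0.02, 0.26, 0.03, 0.026, "no_injury"),
        ]
    ):
        for tp, v in zip(("PRE", "POD0", "POD7", "POD30"), (pre, post, pod7, pod30)):
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "timepoint": tp,
                    "cell_type": "hepatocyte",
                    "fraction": v,
                    "geq_per_ml": v * 1e4,
                    "outcome": outcome,
                    "AST": 40 + v * 1000,
                    "ALT": 35 + v * 900,
                }
            )
    return pd.DataFrame(rows)


def test_pre_post_contrast_on_toy_cohort():
    res, median_fc = pre_post_contrast(_toy_cohort(), "hepatocyte")
    assert res.n == 6 and res.statistic == 21  # all patients increase
    assert median_fc == pytest.approx(np.median([11, 25 / 3, 9.5, 11.5, 7, 13]))
    assert res.exact
    assert res.p_value == pytest.approx(2 / 64)


def test_injury_contrast_separates_toy_arms():
    res = injury_contrast(_toy_cohort(), "hepatocyte")
    assert res.exact and res.statistic == 9  # injured all above non-injured
    assert res.p_value == pytest.approx(0.1)


def test_enzyme_correlation_perfect_monotone_link():
    res = enzyme_correlation(_toy_cohort(), "hepatocyte", "AST", "POD0")
    assert res.statistic == pytest.approx(1.0)
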