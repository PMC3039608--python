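"""Correlations, resampling null, median split, contingency test, stepwise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replifst import (
    derived_allele_test,
    forward_stepwise,
    median_split,
    resampling_mean_fst_test,
    spearman_correlation,
)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_limits():
    x = np.arange(10.0)
    assert spearman_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert spearman_correlation(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_tied_fixture_matches_rank_formula():
    x = np.array([1, 2, 2, 3, 4, 4, 4, 5], float)
    y = np.array([3, 1, 4, 4, 2, 5, 6, 7], float)
    rx = stats.rankdata(x)  # average ranks
    ry = stats.rankdata(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_correlation(x, y)[0] == pytest.approx(expected)


def test_spearman_requires_four_pairs():
    with pytest.raises(ValueError):
        spearman_correlation([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# resampling test


def test_resampling_p_near_half_at_pool_mean():
    rng = np.random.default_rng(0)
    pool = rng.normal(0.1, 0.02, 2000)  # symmetric pool
    res = resampling_mean_fst_test(
        float(pool.mean()), pool, set_size=50, n_resamples=4000, seed=1
    )
    assert abs(res.p - 0.5) < 0.05


def test_resampling_below_pool_minimum_reports_bound():
    pool = np.linspace(0.05, 0.2, 500)
    res = resampling_mean_fst_test(0.01, pool, set_size=40, n_resamples=1000, seed=2)
    assert res.is_bound
    assert str(res) == "< 0.001"
    up = resampling_mean_fst_test(
        0.01, pool, set_size=40, n_resamples=1000, seed=2, tail="upper"
    )
    assert up.p == 1.0


def test_resampling_seed_reproducible_and_validates():
    pool = np.linspace(0, 1, 100)
    a = resampling_mean_fst_test(0.4, pool, 10, n_resamples=500, seed=7)
    b = resampling_mean_fst_test(0.4, pool, 10, n_resamples=500, seed=7)
    assert a.k == b.k
    with pytest.raises(ValueError):
        resampling_mean_fst_test(0.4, pool, 101, seed=0)
    with pytest.raises(ValueError):
        resampling_mean_fst_test(0.4, pool, 10, tail="sideways", seed=0)


# ---------------------------------------------------------------------------
# median split


def test_median_split_ties_in_both_strata():
    df = pd.DataFrame({"replicability_pct": [0.0, 50.0, 100.0]})
    low, high, med = median_split(df)
    assert med == 50.0
    assert low["replicability_pct"].tolist() == [0.0, 50.0]
    assert high["replicability_pct"].tolist() == [50.0, 100.0]


def test_median_split_partitions_without_ties():
    df = pd.DataFrame({"replicability_pct": [10.0, 20.0, 80.0, 90.0]})
    low, high, med = median_split(df)
    assert len(low) + len(high) == 4
    assert set(low["replicability_pct"]) | set(high["replicability_pct"]) == {
        10.0,
        20.0,
        80.0,
        90.0,
    }


# ---------------------------------------------------------------------------
# derived-allele chi-square


def _yates_by_hand(t):
    t = np.asarray(t, float)
    row, col, n = t.sum(1), t.sum(0), t.sum()
    e = np.outer(row, col) / n
    return float(((np.abs(t - e) - 0.5) ** 2 / e).sum())


def test_derived_allele_test_matches_hand_yates_formula():
    t = [[190, 45], [197, 51]]
    chi2, p = derived_allele_test(t)
    assert chi2 == pytest.approx(_yates_by_hand(t))
    assert p == pytest.approx(stats.chi2.sf(_yates_by_hand(t), 1))


def test_equal_proportions_give_null_result():
    chi2, p = derived_allele_test([[80, 20], [160, 40]])
    assert chi2 == pytest.approx(0.0, abs=1e-6)
    assert p > 0.99


def test_statistic_invariant_to_row_swap():
    t = np.array([[190, 45], [197, 51]])
    assert derived_allele_test(t)[0] == pytest.approx(derived_allele_test(t[::-1])[0])


# ---------------------------------------------------------------------------
# forward stepwise


def _stepwise_oracle(X, y, p_enter=0.05, p_remove=0.10):
    """Independent replay of the enter/remove rules via RSS partial-F tests."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    n, m = X.shape

    def rss(cols):
        A = np.column_stack([np.ones(n)] + [Xz[:, j] for j in cols])
        resid = yz - A @ np.linalg.lstsq(A, yz, rcond=None)[0]
        return float(resid @ resid)

    def partial_p(cols_with, j):
        cols_without = [c for c in cols_with if c != j]
        r1, r0 = rss(cols_with), rss(cols_without)
        df2 = n - len(cols_with) - 1
        f = (r0 - r1) / (r1 / df2)
        return float(stats.f.sf(f, 1, df2))

    included: list[int] = []
    while True:
        cand = [(partial_p(included + [j], j), j) for j in range(m) if j not in included]
        cand = [c for c in cand if c[0] < p_enter]
        if not cand:
            break
        included.append(min(cand)[1])
        while len(included) > 1:
            ps = [(partial_p(included, j), j) for j in included]
            worst_p, worst = max(ps)
            if worst_p > p_remove:
                included.remove(worst)
            else:
                break
    return included


def test_single_informative_predictor_selected_with_unit_beta():
    rng = np.random.default_rng(10)
    x = rng.normal(size=60)
    y = 2 * x + rng.normal(scale=0.05, size=60)
    X = pd.DataFrame({"x": x, "noise": rng.normal(size=60)})
    model = forward_stepwise(X, y)
    assert model.predictors == ["x"]
    assert model.betas["x"] == pytest.approx(1.0, abs=0.02)
    assert model.tolerances["x"] == 1.0


def test_two_orthogonal_predictors_selected_with_high_tolerance():
    rng = np.random.default_rng(11)
    n = 80
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = x1 + 0.7 * x2 + rng.normal(scale=0.3, size=n)
    X = pd.DataFrame(
        {"x1": x1, "x2": x2, "junk1": rng.normal(size=n), "junk2": rng.normal(size=n)}
    )
    model = forward_stepwise(X, y)
    # the informative predictors enter first; a junk column may squeak past
    # the 0.05 entry threshold (that is the test's false-entry rate, ~5%)
    assert model.predictors[:2] == ["x1", "x2"]
    assert model.tolerances["x1"] > 0.9 and model.tolerances["x2"] > 0.9
    assert model.adj_r2 <= model.r2


def test_stepwise_matches_independent_enumeration_oracle():
    rng = np.random.default_rng(12)
    n = 50
    for trial in range(8):
        m = int(rng.integers(3, 7))
        X = rng.normal(size=(n, m))
        beta = np.where(rng.random(m) < 0.5, rng.normal(scale=1.0, size=m), 0.0)
        y = X @ beta + rng.normal(scale=1.0, size=n)
        df = pd.DataFrame(X, columns=[f"v{j}" for j in range(m)])
        model = forward_stepwise(df, y)
        oracle = _stepwise_oracle(X, y)
        assert model.predictors == [f"v{j}" for j in oracle], f"trial {trial}"


def test_no_candidate_passing_entry_gives_empty_model():
    rng = np.random.default_rng(13)
    X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    y = rng.normal(size=40)
    model = forward_stepwise(X, y, p_enter=1e-9)
    assert model.empty


def test_stepwise_invariant_to_affine_rescaling():
    rng = np.random.default_rng(14)
    n = 60
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = 1.5 * X["a"] - X["c"] + rng.normal(scale=0.5, size=n)
    base = forward_stepwise(X, y)
    Xs = X.copy()
    Xs["a"] = 1000 * Xs["a"] - 7
    Xs["c"] = 0.001 * Xs["c"] + 42
    scaled = forward_stepwise(Xs, y)
    assert base.predictors == scaled.predictors
    for k in base.betas:
        assert base.betas[k] == pytest.approx(scaled.betas[k], rel=1e-8)


def test_stepwise_requires_enough_rows():
    X = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 5)))
    X.columns = [f"v{j}" for j in range(5)]
    with pytest.raises(ValueError):
        forward_stepwise(X, np.arange(6.0))
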