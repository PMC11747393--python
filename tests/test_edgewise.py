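import numpy as np
import pytest

from pramnet.data_model import ValidationError
from pramnet.edgewise import (
    RankDeficientError,
    build_design,
    fdr_correct,
    fit_edge_glm,
    permutation_pvalue,
    run_edgewise,
)
from pramnet.simulate import SimulationConfig, default_scenarios, simulate_cohort


def _random_instance(rng, n, k):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + rng.normal(size=n)
    return X, y


def _ols_oracle(X, y):
    """Brute-force normal equations (X'X)^-1 X'y with classic OLS errors."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (X.shape[0] - X.shape[1])
    return beta, np.sqrt(np.diag(s2 * xtx_inv))


def test_ols_matches_normal_equation_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(20, 201))
        k = int(rng.integers(2, 7))
        X, y = _random_instance(rng, n, k)
        coef, se = fit_edge_glm(y, X)
        b0, se0 = _ols_oracle(X, y)
        np.testing.assert_allclose(coef, b0, atol=1e-8)
        np.testing.assert_allclose(se, se0, atol=1e-8)


def test_exact_linear_response_recovered_to_machine_precision():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(50), rng.integers(0, 2, 50), rng.normal(size=50)])
    y = 0.3 - 1.7 * X[:, 1] + 0.0 * X[:, 2]
    coef, _ = fit_edge_glm(y, X)
    assert coef[1] == pytest.approx(-1.7, abs=1e-12)


def test_constant_response_gives_zero_slopes():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
    coef, _ = fit_edge_glm(np.full(30, 0.4), X)
    assert coef[1] == pytest.approx(0.0, abs=1e-12)
    assert coef[2] == pytest.approx(0.0, abs=1e-12)


def test_rank_deficiency_names_collinear_columns():
    X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
    with pytest.raises(RankDeficientError, match="collinear"):
        fit_edge_glm(np.zeros(20), X, names=["intercept", "income", "income_x2"])


def test_perfect_fit_attains_minimal_pvalue():
    rng = np.random.default_rng(3)
    x = rng.normal(size=400)
    X = np.column_stack([np.ones(400), x])
    p, beta = permutation_pvalue(x * 1.0, X, tested=1, n_perm=500, seed=0)
    assert beta == pytest.approx(1.0)
    assert p == pytest.approx(1 / 501)


def test_permutation_pvalue_deterministic_and_affine_invariant():
    rng = np.random.default_rng(4)
    n = 120
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=(n, 2))])
    y = rng.normal(size=n)
    p1, _ = permutation_pvalue(y, X, 1, n_perm=300, seed=11)
    p2, _ = permutation_pvalue(y, X, 1, n_perm=300, seed=11)
    p3, _ = permutation_pvalue(3.5 * y - 2.0, X, 1, n_perm=300, seed=11)
    assert p1 == p2 == p3


def test_constant_predictor_rejected():
    X = np.column_stack([np.ones(50), np.full(50, 2.0)])
    with pytest.raises(ValidationError, match="constant"):
        permutation_pvalue(np.random.default_rng(0).normal(size=50), X, 1, n_perm=100)


def test_freedman_lane_agrees_with_simple_scheme():
    """Both permutation schemes are valid under the null and detect the same
    strong signal; their p-values agree in decision on clear cases."""
    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=n)
    C = rng.normal(size=(n, 2))
    X = np.column_stack([np.ones(n), x, C])
    y_strong = 2.0 * x + C @ [0.5, -0.3] + rng.normal(size=n)
    y_null = C @ [0.5, -0.3] + rng.normal(size=n)
    for y, expect_small in ((y_strong, True), (y_null, False)):
        p_simple, _ = permutation_pvalue(y, X, 1, n_perm=500, seed=0, scheme="simple")
        p_fl, _ = permutation_pvalue(y, X, 1, n_perm=500, seed=0, scheme="freedman-lane")
        assert (p_simple < 0.01) == expect_small
        assert (p_fl < 0.01) == expect_small


def _bh_oracle(pvals, alpha):
    """Brute-force step-up: largest i with p_(i) <= i*alpha/m is rejected."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


@pytest.mark.parametrize(
    "pvals,alpha,n_reject",
    [
        ([0.01, 0.02, 0.03, 0.5], 0.05, 3),
        ([1.0] * 10, 0.05, 0),
        ([0.001] * 120, 0.05, 120),
    ],
)
def test_bh_worked_examples(pvals, alpha, n_reject):
    _, reject = fdr_correct(pvals, alpha)
    assert int(reject.sum()) == n_reject


def test_bh_matches_step_up_oracle_on_random_inputs():
    rng = np.random.default_rng(6)
    for _ in range(50):
        p = rng.uniform(1e-4, 1.0, size=int(rng.integers(1, 200)))
        q, reject = fdr_correct(p, 0.05)
        np.testing.assert_array_equal(reject, _bh_oracle(p, 0.05))
        assert np.all((q > 0) & (q <= 1))


def test_bh_rejections_monotone_in_pvalues():
    rng = np.random.default_rng(7)
    p = rng.uniform(0.001, 1.0, size=60)
    _, before = fdr_correct(p, 0.05)
    p2 = p.copy()
    p2[rng.integers(0, 60)] /= 10
    _, after = fdr_correct(p2, 0.05)
    assert set(np.flatnonzero(before)) <= set(np.flatnonzero(after))


def test_fdr_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_correct([0.0, 0.5], 0.05)


def test_design_excludes_mediator_from_race_model(small_null_cohort):
    d_race = build_design(small_null_cohort, "race")
    assert "news_bias" not in d_race.columns
    assert d_race.columns[:2] == ("intercept", "race")
    d_news = build_design(small_null_cohort, "news_bias")
    assert "race" in d_news.columns
    assert d_news.columns[1] == "news_bias"


def test_run_edgewise_recovers_planted_effects_small():
    cfg = SimulationConfig(
        n_per_group=120,
        direct_effects={0: 1.5, 5: -1.5},
        noise_sd=1.5,
        mediator_sd=0.5,
    )
    co = simulate_cohort(cfg, seed=8)
    # permutation p-values are bounded below by 1/(n_perm+1); with only two
    # true effects in a family of 120 the BH threshold needs p < 2*.05/120,
    # so enough permutations are required for any discovery at all
    res = run_edgewise(co, predictors=("race",), n_perm=5000, seed=8)
    sig = set(res.significant_pairs("race"))
    assert {0, 5} <= sig
    assert len(sig) <= 6  # planted plus at most a few false alarms
    df = res.for_predictor("race")
    # edge weights are distances: positive rating effect -> negative beta
    assert df.loc[df.pair == 0, "beta"].iloc[0] < 0
    assert df.loc[df.pair == 5, "beta"].iloc[0] > 0


def test_run_edgewise_independent_of_edge_evaluation_order():
    """Per-edge seed substreams: the p-value of an edge does not depend on
    which other predictors or edges were evaluated in the same run."""
    co = simulate_cohort(SimulationConfig(n_per_group=40, mediator_sd=0.6), seed=10)
    both = run_edgewise(co, predictors=("race", "news_bias"), n_perm=200, seed=3)
    race_only = run_edgewise(co, predictors=("race",), n_perm=200, seed=3)
    a = both.for_predictor("race")["p_value"].to_numpy()
    b = race_only.for_predictor("race")["p_value"].to_numpy()
    np.testing.assert_array_equal(a, b)
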