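import numpy as np
import pytest

from pramnet.data_model import ValidationError
from pramnet.edgewise import run_edgewise
from pramnet.graphs import EdgeWeightMatrix
from pramnet.mediation import (
    classify_mediation,
    mediation_paths,
    mediation_permutation,
    run_mediation_screen,
    sobel_test,
)
from pramnet.simulate import SimulationConfig, default_scenarios, simulate_cohort


def _random_mediation_data(rng, n=150, with_cov=True):
    x = rng.integers(0, 2, n).astype(float)
    C = rng.normal(size=(n, 3)) if with_cov else None
    m = 0.5 * x + rng.normal(size=n)
    y = 0.4 * x + 0.7 * m + rng.normal(size=n)
    if with_cov:
        y += C @ [0.2, -0.1, 0.3]
        m += C @ [0.1, 0.2, -0.2]
    return x, m, y, C


def test_total_effect_decomposes_exactly():
    """c = c' + a*b holds identically for nested OLS fits sharing covariates."""
    rng = np.random.default_rng(0)
    for with_cov in (True, False):
        for _ in range(10):
            x, m, y, C = _random_mediation_data(rng, with_cov=with_cov)
            paths = mediation_paths(x, m, y, C)
            assert abs(paths.c - paths.c_prime - paths.a * paths.b) < 1e-10


def test_response_in_span_of_x_gives_zero_b_path():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 80).astype(float)
    m = rng.normal(size=80)
    y = 2.0 * x - 1.0  # exactly linear in x: nothing left for the mediator
    paths = mediation_paths(x, m, y)
    assert paths.b == pytest.approx(0.0, abs=1e-10)
    assert paths.indirect == pytest.approx(0.0, abs=1e-10)
    assert paths.c_prime == pytest.approx(paths.c, abs=1e-10)


def test_sobel_worked_example_and_limits():
    z, p = sobel_test(0.5, 0.1, 0.4, 0.1)
    assert z == pytest.approx(0.2 / np.sqrt(0.0041), abs=1e-4)
    assert z == pytest.approx(3.1235, abs=1e-3)
    assert p < 0.01

    z0, p0 = sobel_test(0.0, 0.1, 1.0, 0.1)
    assert (z0, p0) == (0.0, 1.0)
    z_neg, _ = sobel_test(-0.5, 0.1, 0.4, 0.1)
    assert np.sign(z_neg) == np.sign(-0.5 * 0.4)
    with pytest.raises(ValueError):
        sobel_test(0.5, 0.0, 0.4, 0.1)


def test_mediation_permutation_deterministic_and_detects_strong_effect():
    rng = np.random.default_rng(2)
    x, m, y, C = _random_mediation_data(rng, n=400)
    p1, ind1 = mediation_permutation(x, m, y, C, n_perm=500, seed=5)
    p2, ind2 = mediation_permutation(x, m, y, C, n_perm=500, seed=5)
    assert (p1, ind1) == (p2, ind2)
    assert p1 == pytest.approx(1 / 501)  # strong planted indirect path
    paths = mediation_paths(x, m, y, C)
    assert ind1 == pytest.approx(paths.indirect, abs=1e-10)


def test_mediation_permutation_calibrated_under_null():
    """Mediator unrelated to x and y: rejection rate approximates alpha."""
    rng = np.random.default_rng(3)
    rejections = 0
    reps = 300
    for _ in range(reps):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        m = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        p, _ = mediation_permutation(x, m, y, n_perm=120, seed=rng.integers(2**31))
        rejections += p <= 0.05
    rate = rejections / reps
    assert 0.02 <= rate <= 0.09


def test_constant_mediator_rejected():
    x = np.array([0.0, 1.0] * 30)
    with pytest.raises(ValidationError, match="constant"):
        mediation_permutation(x, np.full(60, 2.0), x, n_perm=100)


@pytest.mark.parametrize(
    "q_ind,q_dir,flag,label",
    [
        (0.01, 0.30, True, "full"),
        (0.01, 0.01, True, "partial"),
        (0.30, 0.01, True, "unmediated"),
        (0.30, 0.30, True, "unmediated"),
        (0.01, 0.30, False, "not_race_differing"),
    ],
)
def test_classification_rules(q_ind, q_dir, flag, label):
    assert classify_mediation(q_ind, q_dir, flag, alpha=0.05) == label


def test_empty_screen_gives_empty_table(small_null_cohort):
    res = run_mediation_screen(small_null_cohort, [], n_perm=100, seed=0)
    assert len(res.table) == 0
    assert res.label_counts() == {
        "not_race_differing": 0, "unmediated": 0, "partial": 0, "full": 0
    }


def test_screen_labels_invariant_to_input_order(small_null_cohort):
    a = run_mediation_screen(small_null_cohort, [5, 1, 9], n_perm=100, seed=1)
    b = run_mediation_screen(small_null_cohort, [9, 5, 1], n_perm=100, seed=1)
    assert a.table.equals(b.table)


def test_fully_mediated_scenario_recovery():
    """With no direct path planted, c' is indistinguishable from zero while
    the indirect effect matches the planted a*b."""
    cfg = default_scenarios()["fully_mediated"]
    co = simulate_cohort(cfg, seed=6)
    mask = co.scored_mask()
    x = co.demographics.loc[mask, "race"].to_numpy(float)
    m = co.news_bias[mask]
    w = EdgeWeightMatrix.from_ratings(co.ratings).values[mask]
    edge = next(iter(cfg.mediation_labels))
    paths = mediation_paths(x, m, w[:, edge])
    assert abs(paths.c_prime) < 1.96 * paths.se_c_prime
    # planted indirect on the weight scale: the rating-scale slope flips sign
    # through the similarity->distance transform (divide by -14)
    planted = cfg.a_path * (-cfg.news_effects[edge] / 14.0)
    assert np.sign(paths.indirect) == np.sign(planted)
    assert abs(paths.indirect) > 3 * np.hypot(paths.se_a * paths.b, paths.se_b * paths.a)


def test_classification_monotone_in_b_path():
    """Strengthening the mediator->outcome slope never demotes an edge from
    full/partial back to unmediated (same noise realization)."""
    ranks = {"unmediated": 0, "partial": 1, "full": 1}
    observed = []
    for b in (0.0, 0.45, 0.9, 1.35):
        cfg = SimulationConfig(
            n_per_group=223,
            news_effects={0: b} if b else {},
            mediation_labels={0: "full"} if b else {},
            a_path=-0.6,
            mediator_mean=2.6,
            mediator_sd=1.0,
            noise_sd=1.5,
        )
        co = simulate_cohort(cfg, seed=13)
        res = run_mediation_screen(co, [0], n_perm=300, seed=13)
        observed.append(ranks[res.table["label"].iloc[0]]
                        if res.table["label"].iloc[0] != "not_race_differing" else 0)
    assert observed == sorted(observed)


def test_sobel_and_permutation_agree_on_mediated_edges():
    """Large-sample concordance of the two indirect-effect tests on edges
    with a real mediated path. (On screened edges with a strong group->
    mediator path but a null mediator->outcome path the mediator-permutation
    null is anti-conservative relative to Sobel, so concordance is only
    expected where mediation is present.)"""
    cfg = default_scenarios()["partially_mediated"]
    co = simulate_cohort(cfg, seed=21)
    screen = run_edgewise(co, predictors=("race",), n_perm=1000, seed=21)
    med = run_mediation_screen(
        co, screen.significant_pairs("race"), n_perm=1000, seed=21
    )
    t = med.table
    agree = ((t["sobel_p"] <= 0.05) == (t["p_indirect"] <= 0.05)).mean()
    assert agree >= 0.9
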