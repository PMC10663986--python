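"""Loss-function fixtures and invariants, checked against hand evaluations
and an independent double-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathsurv.losses import (
    TimeGrid,
    balanced_class_weights,
    cox_gradient,
    cox_negative_log_partial_likelihood,
    deephit_loss,
    interval_fraction,
    pc_hazard_loss,
    weighted_binary_cross_entropy,
)

from conftest import naive_cox_loss


# -- Cox partial likelihood ----------------------------------------------


def test_cox_single_event_self_risk_set():
    for r in (-3.0, 0.0, 7.5):
        assert cox_negative_log_partial_likelihood([r], [1], [5.0]) == pytest.approx(0.0)


def test_cox_hand_fixture_log2():
    val = cox_negative_log_partial_likelihood([0.0, 0.0], [1, 1], [1.0, 2.0])
    assert val == pytest.approx(np.log(2), abs=1e-12)


def test_cox_shift_invariance_and_permutation():
    rng = np.random.default_rng(2)
    h = rng.normal(size=10)
    e = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
    d = rng.uniform(1, 50, 10)
    base = cox_negative_log_partial_likelihood(h, e, d)
    assert cox_negative_log_partial_likelihood(h + 13.7, e, d) == pytest.approx(base)
    perm = rng.permutation(10)
    assert cox_negative_log_partial_likelihood(h[perm], e[perm], d[perm]) == pytest.approx(base)


def test_cox_matches_naive_oracle_with_ties():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(2, 9)
        h = rng.normal(size=n)
        e = rng.integers(0, 2, size=n)
        e[rng.integers(n)] = 1
        d = rng.integers(1, 4, size=n).astype(float)  # heavy ties
        assert cox_negative_log_partial_likelihood(h, e, d) == pytest.approx(
            naive_cox_loss(h, e, d), abs=1e-10)


def test_cox_zero_events_is_error():
    with pytest.raises(ValueError, match="zero events"):
        cox_negative_log_partial_likelihood([1.0, 2.0], [0, 0], [1.0, 2.0])


def test_cox_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    h = rng.normal(size=6)
    e = np.array([1, 1, 0, 1, 0, 1])
    d = rng.uniform(1, 9, 6)
    g = cox_gradient(h, e, d)
    for i in range(6):
        step = np.zeros(6)
        step[i] = 1e-6
        num = (cox_negative_log_partial_likelihood(h + step, e, d)
               - cox_negative_log_partial_likelihood(h - step, e, d)) / 2e-6
        assert g[i] == pytest.approx(num, abs=1e-6)


# -- time grid -----------------------------------------------------------


def test_interval_fraction_fixtures():
    grid = TimeGrid([0.0, 10.0, 20.0])
    k, r = interval_fraction(15.0, grid)
    assert (k, r) == (2, 0.5)
    k, r = interval_fraction(10.0, grid)  # left boundary of interval 2
    assert (k, r) == (2, 0.0)
    k, r = interval_fraction(20.0, grid)  # T_final closes the last interval
    assert (k, r) == (2, 1.0)
    k, r = interval_fraction(0.0, grid)
    assert (k, r) == (1, 0.0)


def test_interval_fraction_clamps_outside_grid():
    grid = TimeGrid([0.0, 10.0])
    assert interval_fraction(25.0, grid) == (1, 1.0)
    assert interval_fraction(-2.0, grid) == (1, 0.0)


def test_grid_validation():
    with pytest.raises(ValueError, match="increasing"):
        TimeGrid([0.0, 5.0, 5.0])
    with pytest.raises(ValueError, match="nonnegative"):
        TimeGrid([-1.0, 5.0])
    g = TimeGrid.uniform(100.0, 4)
    assert g.m == 4
    np.testing.assert_allclose(g.widths, 25.0)


def test_bin_index_right_continuous():
    g = TimeGrid([0.0, 10.0, 20.0])
    np.testing.assert_array_equal(g.bin_index([0.0, 5.0, 10.0, 10.1, 20.0, 99.0]),
                                  [1, 1, 1, 2, 2, 2])


# -- DeepHit -------------------------------------------------------------


def test_deephit_censored_hand_fixture():
    # one censored sample, mass (0.5, 0.5), in bin 1: loss_L = -log S(T1) = -log 0.5
    masses = np.array([[0.5, 0.5]])
    assert deephit_loss(masses, [0], [1], alpha=1.0, sigma=0.1) == pytest.approx(
        -np.log(0.5), abs=1e-10)


def test_deephit_event_hand_fixture():
    # event in bin 2 with mass 0.3 there: loss_L = -log 0.3; single sample, no pairs
    masses = np.array([[0.2, 0.3, 0.5]])
    for alpha in (1.0, 0.25):
        assert deephit_loss(masses, [1], [2], alpha=alpha, sigma=0.1) == pytest.approx(
            -alpha * np.log(0.3), abs=1e-10)


def test_deephit_composite_two_sample_hand_value():
    # event in bin 1 vs censored in bin 2: one comparable pair
    masses = np.array([[0.6, 0.3, 0.1], [0.1, 0.2, 0.7]])
    sigma = 0.5
    expected_l = -np.log(0.6) - np.log(1 - 0.1 - 0.2)  # event mass; S_2(T_2)
    s_own = 1 - 0.6  # S_1(T_1)
    s_other_at_1 = 1 - 0.1  # S_2(T_1)
    expected_rank = np.exp((s_own - s_other_at_1) / sigma)
    got = deephit_loss(masses, [1, 0], [1, 2], alpha=0.3, sigma=sigma)
    assert got == pytest.approx(0.3 * expected_l + 0.7 * expected_rank, abs=1e-10)


def test_deephit_sigma_limit_saturates_ranking():
    # identical masses, sigma -> inf: each comparable pair contributes exp(0)=1
    masses = np.tile([[0.25, 0.25, 0.5]], (3, 1))
    got = deephit_loss(masses, [1, 1, 0], [1, 2, 3], alpha=0.0, sigma=1e12)
    assert got == pytest.approx(3.0, abs=1e-9)  # pairs: (1,2),(1,3),(2,3)


def test_deephit_mass_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        deephit_loss(np.array([[0.5, 0.2]]), [1], [1])
    with pytest.raises(ValueError, match="bin_index"):
        deephit_loss(np.array([[0.5, 0.5]]), [1], [3])


def test_deephit_likelihood_rewards_correct_bin():
    # moving mass toward the true event bin lowers loss_L
    e, k = [1], [2]
    worse = deephit_loss(np.array([[0.5, 0.2, 0.3]]), e, k, alpha=1.0)
    better = deephit_loss(np.array([[0.3, 0.5, 0.2]]), e, k, alpha=1.0)
    assert better < worse


# -- PC-Hazard -----------------------------------------------------------


def test_pc_hazard_event_at_boundary_fixture():
    # event exactly at T1 on grid (0,1) with eta=1: -[log 1 - 1*1*1] = 1
    grid = TimeGrid([0.0, 1.0])
    assert pc_hazard_loss(np.array([[1.0]]), [1], [1.0], grid) == pytest.approx(1.0, abs=1e-12)


def test_pc_hazard_censored_at_origin_contributes_zero():
    grid = TimeGrid([0.0, 1.0, 2.0])
    assert pc_hazard_loss(np.array([[3.0, 2.0]]), [0], [0.0], grid) == pytest.approx(0.0)


def test_pc_hazard_two_sample_hand_value():
    # grid (0, 2, 6); sample 1: event at t=3 (kappa=2, rho=0.25), etas (0.5, 1.5)
    #   -> log 1.5 - 1.5*0.25*4 - 0.5*2 = log 1.5 - 1.5 - 1.0
    # sample 2: censored at t=2 (kappa=1 boundary? t=2 -> kappa=2, rho=0)
    #   -> -0.5*2 with etas (0.5, 2.0): only full first interval
    grid = TimeGrid([0.0, 2.0, 6.0])
    etas = np.array([[0.5, 1.5], [0.5, 2.0]])
    s1 = np.log(1.5) - 1.5 * 0.25 * 4.0 - 0.5 * 2.0
    s2 = -0.5 * 2.0
    expected = -(s1 + s2) / 2.0
    assert pc_hazard_loss(etas, [1, 0], [3.0, 2.0], grid) == pytest.approx(expected, abs=1e-10)


def test_pc_hazard_rate_duration_invariance_for_censored():
    # doubling interval widths and halving rates leaves censored terms unchanged
    rng = np.random.default_rng(0)
    etas = rng.uniform(0.1, 2.0, size=(4, 3))
    d = np.array([1.0, 2.5, 3.0, 1.7])
    e = [0, 0, 0, 0]
    a = pc_hazard_loss(etas, e, d, TimeGrid([0.0, 1.0, 2.0, 3.0]))
    b = pc_hazard_loss(etas / 2.0, e, 2 * d, TimeGrid([0.0, 2.0, 4.0, 6.0]))
    assert a == pytest.approx(b, abs=1e-12)


def test_pc_hazard_rejects_negative_rates():
    with pytest.raises(ValueError, match="nonnegative"):
        pc_hazard_loss(np.array([[-0.1]]), [1], [0.5], TimeGrid([0.0, 1.0]))


# -- weighted binary cross-entropy ---------------------------------------


def test_bce_fixtures():
    assert weighted_binary_cross_entropy([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-6)
    assert weighted_binary_cross_entropy([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))


def test_bce_weight_equals_replication():
    # weight 3 on positives == each positive sample appearing three times
    p = np.array([0.8, 0.3, 0.6])
    y = np.array([1, 0, 1])
    weighted = weighted_binary_cross_entropy(p, y, (1.0, 3.0)) * 3
    p_rep = np.array([0.8, 0.8, 0.8, 0.3, 0.6, 0.6, 0.6])
    y_rep = np.array([1, 1, 1, 0, 1, 1, 1])
    replicated = weighted_binary_cross_entropy(p_rep, y_rep, (1.0, 1.0)) * 7
    assert weighted == pytest.approx(replicated, abs=1e-10)


def test_balanced_class_weights():
    w0, w1 = balanced_class_weights([1, 1, 1, 0])
    assert (w0, w1) == (2.0, 2.0 / 3.0)
    with pytest.raises(ValueError):
        balanced_class_weights([1, 1])


# -- property tests ------------------------------------------------------


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 8), st.integers(0, 1000))
def test_cox_oracle_property(n, seed):
    """Vectorized Cox loss equals the double-loop oracle on random instances."""
    rng = np.random.default_rng(seed)
    h = rng.normal(size=n)
    e = rng.integers(0, 2, size=n)
    e[rng.integers(n)] = 1
    d = rng.choice([1.0, 2.0, 3.0, 4.5, 7.0], size=n)
    assert cox_negative_log_partial_likelihood(h, e, d) == pytest.approx(
        naive_cox_loss(h, e, d), abs=1e-10)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(0.05, 0.95), st.integers(1, 500))
def test_interval_fraction_bounds(frac, seed):
    rng = np.random.default_rng(seed)
    bounds = np.cumsum(rng.uniform(0.5, 3.0, size=5))
    grid = TimeGrid(np.r_[0.0, bounds])
    t = frac * bounds[-1]
    k, rho = interval_fraction(t, grid)
    assert 1 <= k <= grid.m
    assert 0.0 <= rho <= 1.0
    # reconstruct t from (kappa, rho)
    recon = grid.boundaries[k - 1] + rho * grid.widths[k - 1]
    assert recon == pytest.approx(t, abs=1e-9)
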