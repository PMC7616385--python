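import math

import numpy as np
import pytest

from sociowalk.belief import (
    Belief,
    InsufficientDataError,
    SensedData,
    belief_update,
    fit_polynomial,
    model_fidelity,
    sense,
    solve_potential_center,
    tricube_weights,
)


def _data(points, sensor_x=0):
    if not points:
        return SensedData(np.array([]), np.array([]), sensor_x)
    xs, Ss = zip(*points)
    return SensedData(np.array(xs, float), np.array(Ss, float), sensor_x)


# ---------------------------------------------------------------- sensing


def test_sense_lone_agent_is_empty():
    d = sense(0, np.array([42]), np.array([1.0]), h=5)
    assert d.n == 0


def test_sense_excludes_self_and_respects_radius():
    x = np.array([0, 3, 10])
    d = sense(0, x, np.array([0.0, 1.0, 2.0]), h=5)
    assert list(d.xs) == [3] and list(d.Ss) == [1.0]


def test_sense_boundary_is_inclusive():
    x = np.array([0, 5])
    d = sense(0, x, np.array([0.0, 1.0]), h=5)
    assert list(d.xs) == [5]


# ---------------------------------------------------------------- fitting


def test_fit_exact_line():
    b = fit_polynomial(_data([(0, 0), (1, 1), (2, 2)]), order=1)
    assert b.beta0 == pytest.approx(0.0, abs=1e-12)
    assert b.beta1 == pytest.approx(1.0, abs=1e-12)


def test_fit_exact_parabola():
    b = fit_polynomial(_data([(-1, 9), (0, 10), (1, 9)]), order=2)
    assert (b.beta0, b.beta1, b.beta2) == pytest.approx((10.0, 0.0, -1.0), abs=1e-10)


def test_fit_is_independent_of_sensor_offset():
    """Absolute-coordinate coefficients do not depend on where the sensor sits."""
    pts = [(3, 1.0), (5, 2.5), (9, 1.5), (12, 4.0), (15, 2.0)]
    b1 = fit_polynomial(_data(pts, sensor_x=0), order=2)
    b2 = fit_polynomial(_data(pts, sensor_x=9), order=2)
    assert (b1.beta0, b1.beta1, b1.beta2) == pytest.approx(
        (b2.beta0, b2.beta1, b2.beta2), rel=1e-9, abs=1e-9
    )


@pytest.mark.parametrize("order", [1, 2])
def test_fit_matches_normal_equations_oracle(order, rng):
    """Weighted fits agree with an independent lstsq solve to 1e-8 relative."""
    for _ in range(200):
        n = rng.integers(order + 2, 15)
        xs = rng.choice(np.arange(-30, 31), size=n, replace=False).astype(float)
        Ss = rng.normal(5.0, 3.0, n)
        w = rng.uniform(0.1, 2.0, n)
        data = SensedData(xs, Ss, sensor_x=int(rng.integers(-5, 6)))
        b = fit_polynomial(data, order=order, weights=w)
        A = np.vander(xs, order + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], Ss * sw, rcond=None)
        mine = np.array([b.beta0, b.beta1, b.beta2])[: order + 1]
        assert np.linalg.norm(mine - coef) <= 1e-8 * max(np.linalg.norm(coef), 1.0)


def test_fit_insufficient_data_raises():
    with pytest.raises(InsufficientDataError):
        fit_polynomial(_data([(0, 1), (1, 2)]), order=2)  # underdetermined
    with pytest.raises(InsufficientDataError):
        fit_polynomial(_data([(0, 1), (0, 2), (1, 3), (1, 0)]), order=2)  # 2 distinct


def test_update_applies_stricter_sufficiency_than_raw_fit():
    # 3 exact parabola points: a raw fit succeeds, the update does not
    pts = [(-1, 9), (0, 10), (1, 9)]
    assert fit_polynomial(_data(pts), order=2).beta2 == pytest.approx(-1.0)
    b, allowed = belief_update(_data(pts), h=10)
    assert b.is_zero and not allowed


def test_tricube_weights_decay_to_zero_at_the_radius():
    d = _data([(0, 1), (5, 1), (10, 1)])
    w = tricube_weights(d, h=10)
    assert w[0] == 1.0 and w[2] == 0.0 and 0 < w[1] < 1


# ---------------------------------------------------------------- fidelity


def test_fidelity_of_exact_fit_is_one():
    d = _data([(-1, 9), (0, 10), (1, 9), (2, 6)])
    b = fit_polynomial(d, order=2)
    assert model_fidelity(d, b) == pytest.approx(1.0, abs=1e-9)


def test_fidelity_of_mean_belief_is_zero():
    d = _data([(0, 0), (1, 1), (2, 2)])
    flat = Belief(order=1, beta0=1.0, beta1=0.0)  # constant at the mean
    assert model_fidelity(d, flat) == pytest.approx(0.0, abs=1e-12)


def test_fidelity_of_zero_belief_on_a_line():
    d = _data([(0, 0), (1, 1), (2, 2)])
    assert model_fidelity(d, Belief.zero()) == pytest.approx(-1.5)


def test_fidelity_zero_variance_sentinel():
    d = _data([(0, 4), (1, 4), (2, 4)])
    assert model_fidelity(d, Belief(order=1, beta0=4.0, beta1=0.0)) == 1.0
    assert model_fidelity(d, Belief.zero()) == -math.inf


def test_least_squares_fit_maximises_fidelity(rng):
    """No same-order polynomial beats the uniform-weight LS fit's fidelity."""
    for _ in range(20):
        n = int(rng.integers(6, 12))
        xs = rng.choice(np.arange(-10, 11), size=n, replace=False).astype(float)
        Ss = rng.normal(0, 2, n)
        d = SensedData(xs, Ss, 0)
        b = fit_polynomial(d, order=2)
        phi_star = model_fidelity(d, b)
        for _ in range(25):
            alt = Belief(
                order=2,
                beta0=b.beta0 + rng.normal(0, 0.5),
                beta1=b.beta1 + rng.normal(0, 0.5),
                beta2=min(b.beta2 + rng.normal(0, 0.5), 0.0),
            )
            assert model_fidelity(d, alt) <= phi_star + 1e-12


# ------------------------------------------------------------- belief_update


def test_update_with_empty_data_resets_belief():
    b, allowed = belief_update(_data([]), h=10)
    assert b.is_zero and not allowed


def test_update_falls_back_to_order_one_on_measured_minimum():
    pts = [(-1, 1), (0, 0), (1, 1), (2, 4)]
    b, allowed = belief_update(_data(pts), h=10)
    assert allowed and b.order == 1
    oracle = fit_polynomial(_data(pts), order=1)
    assert (b.beta0, b.beta1) == pytest.approx((oracle.beta0, oracle.beta1))


def test_update_keeps_concave_quadratic():
    pts = [(x, 10 - x * x) for x in (-2, -1, 0, 1, 2)]
    b, allowed = belief_update(_data(pts), h=10)
    assert allowed and b.order == 2
    assert b.beta2 == pytest.approx(-1.0, abs=1e-9)
    assert b.fidelity == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------- centre solve


def test_center_at_vertex_when_rank_exceeds_belief():
    b = Belief(order=2, beta0=10.0, beta1=0.0, beta2=-1.0)  # 10 - x^2
    assert solve_potential_center(15.0, b, x_k=7) == 0


def test_center_at_nearer_root():
    b = Belief(order=2, beta0=10.0, beta1=0.0, beta2=-1.0)
    assert solve_potential_center(6.0, b, x_k=1) == 2
    assert solve_potential_center(6.0, b, x_k=-1) == -2


def test_center_linear_inversion():
    b = Belief(order=1, beta0=0.0, beta1=2.0)
    assert solve_potential_center(4.0, b, x_k=100) == 2


def test_center_degenerate_flat_belief_gives_no_update():
    b = Belief(order=1, beta0=3.0, beta1=0.0)
    assert solve_potential_center(4.0, b, x_k=0) is None


def test_center_matches_exhaustive_lattice_search(rng):
    """Analytic solve equals brute-force argmin over a wide lattice window."""
    h = 50
    for _ in range(300):
        beta2 = -rng.uniform(0.01, 2.0)
        beta1 = rng.normal(0, 5.0)
        beta0 = rng.uniform(0, 50.0)
        x_k = int(rng.integers(-20, 21))
        S_k = rng.uniform(0, 60.0)
        b = Belief(order=2, beta0=beta0, beta1=beta1, beta2=beta2)
        x_star = solve_potential_center(S_k, b, x_k, rng)
        grid = np.arange(x_k - 10 * h, x_k + 10 * h + 1)
        obj = np.abs(S_k - b.predict(grid))
        # rounding a continuous minimiser costs at most half a site of local
        # slope plus the curvature correction
        eps = 0.5 * abs(beta1 + 2 * beta2 * x_star) + 0.25 * abs(beta2)
        assert abs(S_k - b.predict(x_star)) <= obj.min() + eps + 1e-9
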