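import math

import numpy as np
import pytest

from sociowalk.belief import SensedData, belief_update
from sociowalk.params import SimParams
from sociowalk.simulator import (
    PopulationState,
    initialise,
    log_snapshot_times,
    run,
    step,
)


def _pinned_state(xs, Ss):
    """A state whose agents cannot move (x* on x, meant for L=1 runs)."""
    x = np.asarray(xs, dtype=np.int64)
    n = x.size
    return PopulationState(
        t=0, x=x.copy(), S=np.asarray(Ss, dtype=float),
        order=np.zeros(n, dtype=np.int64),
        b0=np.zeros(n), b1=np.zeros(n), b2=np.zeros(n),
        phi=np.full(n, np.nan), xstar=x.copy(),
    )


# ------------------------------------------------------------- initialise


def test_initialise_reference_conditions():
    p = SimParams(k_h=0.3, k_L=1.0)  # N=100, rho0=0.05 -> A0=2000
    st = initialise(p, np.random.default_rng(0))
    assert st.N == 100
    assert np.all(np.abs(st.x) <= 1000)
    assert np.all(st.S == 0.0)
    assert np.array_equal(st.xstar, st.x)
    assert np.all(st.order == 0)


def test_initialise_tiny_interval_discretisation():
    p = SimParams(N=2, rho0=1.0, k_h=1.0, k_L=1.0)
    for seed in range(20):
        st = initialise(p, np.random.default_rng(seed))
        assert set(st.x.tolist()) <= {-1, 0, 1}


def test_initialise_is_deterministic():
    p = SimParams(k_h=0.3, k_L=1.0)
    a = initialise(p, np.random.default_rng(7))
    b = initialise(p, np.random.default_rng(7))
    assert np.array_equal(a.x, b.x)


# ------------------------------------------------------------------- step


def test_sensing_disabled_freezes_beliefs_and_centres(small_params):
    p = small_params.replace(r=0.0, T=500)
    res = run(p, seed=3)
    st = res.final_state
    assert np.all(st.order == 0)
    assert np.all(np.isnan(st.phi))
    # potentials never moved: x* is still the initial position draw
    init = initialise(p, np.random.default_rng(3))
    assert np.array_equal(st.xstar, init.x)
    assert np.all(np.abs(st.x - st.xstar) < p.L)


def test_spread_bounded_without_sensing(small_params):
    p = small_params.replace(r=0.0, T=2000)
    res = run(p, seed=11)
    st = res.final_state
    first = initialise(p, np.random.default_rng(11))
    spread0 = first.x.max() - first.x.min()
    assert st.x.max() - st.x.min() <= spread0 + 2 * (p.L - 1)


def test_colocated_pair_produces_exactly_one_winner(rng):
    p = SimParams(N=2, rho0=1.0, k_h=1.0, L=1, r=0.0)
    st = _pinned_state([0, 0], [0.0, 0.0])
    step(st, p, rng)
    assert sorted(st.S.tolist()) == [0.0, 1.0]
    assert st.t == 1


def test_low_fidelity_belief_not_retained_before_waiting_time(rng):
    """Before t_c a Phi < 0 measurement leaves belief and centre untouched."""
    # near neighbours flat at 0, far neighbours at rank 100: the tricube fit
    # hugs the near points, so the unweighted fidelity is negative
    xs = [0, -2, -1, 1, 2, -99, 99]
    Ss = [5.0, 0.0, 0.0, 0.0, 0.0, 100.0, 100.0]
    d = SensedData(np.array(xs[1:], float), np.array(Ss[1:]), sensor_x=0)
    bel, allowed = belief_update(d, weights="tricube", h=100)
    assert allowed and bel.fidelity < 0  # the scenario really is low-fidelity

    p = SimParams(N=7, rho0=1.0, h=100, L=1, r=1.0, t_c=10**6,
                  weights="tricube")
    st = _pinned_state(xs, Ss)
    step(st, p, rng)
    assert st.order[0] == 0 and st.xstar[0] == 0  # discarded

    p_late = p.replace(t_c=0)
    st2 = _pinned_state(xs, Ss)
    step(st2, p_late, rng)
    assert st2.order[0] != 0  # after t_c the same measurement is adopted


def test_fidelity_nonnegative_under_uniform_weights(small_params):
    """Uniform-weight least squares with intercept cannot give Phi < 0."""
    p = small_params.replace(T=1500, weights="uniform")
    res = run(p, seed=5)
    phis = res.final_state.phi
    assert np.all(np.isnan(phis) | (phis >= 0.0) | np.isinf(phis))


# -------------------------------------------------------------------- run


def test_run_is_deterministic(small_params):
    a = run(small_params, seed=9)
    b = run(small_params, seed=9)
    assert np.array_equal(a.final_state.x, b.final_state.x)
    assert np.array_equal(a.final_state.S, b.final_state.S)
    assert np.array_equal(a.series.delta, b.series.delta)


@pytest.mark.parametrize("pair_mode", ["all", "single"])
@pytest.mark.parametrize("center_rule", ["window", "clamp"])
def test_kernel_matches_reference_stepper(pair_mode, center_rule):
    """The compiled loop and the pure-Python stepper produce bit-identical
    trajectories from the same seed."""
    p = SimParams(N=20, rho0=0.5, k_h=1.0, k_L=1.0, T=1500, t_c=300,
                  r=0.05, pair_mode=pair_mode, center_rule=center_rule)
    rk = run(p, seed=21, use_kernel=True)
    rp = run(p, seed=21, use_kernel=False)
    for attr in ("x", "S", "xstar", "order", "b0", "b1", "b2"):
        a = getattr(rk.final_state, attr)
        b = getattr(rp.final_state, attr)
        assert np.array_equal(a, b), attr
    assert np.array_equal(rk.series.delta, rp.series.delta)


def test_agents_always_inside_their_potentials(small_params):
    p = small_params.replace(T=3000)
    res = run(p, seed=2, record_snapshots=True)
    st = res.final_state
    assert np.all(np.abs(st.x - st.xstar) < p.L)


def test_retained_beliefs_never_hold_a_minimum(small_params):
    """Agent-held order-2 beliefs are concave: the measured-minimum fallback
    guarantees beta2 <= 0 for every retained quadratic."""
    p = small_params.replace(T=3000)
    st = run(p, seed=13).final_state
    quad = st.order == 2
    assert quad.any()
    assert np.all(st.b2[quad] <= 0.0)
    zero = st.order == 0
    assert np.all(st.b0[zero] == 0) and np.all(st.b2[zero] == 0)


def test_rank_conservation_over_a_full_run(small_params):
    p = small_params.replace(T=2000)
    res = run(p, seed=4)
    # delta_plus=1, delta_minus=0: total rank == number of realised contests
    assert res.final_state.S.sum() == res.n_interactions
    assert np.all(res.final_state.S >= 0)


def test_rank_growth_saturates_once_gaps_reach_the_threshold():
    """In a converged cohesive run the interaction gate shuts down rank
    growth: neighbouring ranks differ by ~dS_max, so contests die out and
    total rank stalls (late growth a small fraction of early growth)."""
    p = SimParams(N=20, rho0=0.5, k_h=1.0, k_L=1.0, T=150_000, t_c=1500,
                  dS_max=20.0)
    first = run(p.replace(T=75_000), seed=0)
    full = run(p, seed=0)
    early_growth = first.final_state.S.sum()
    late_growth = full.final_state.S.sum() - early_growth
    assert late_growth < 0.2 * early_growth
    # and the converged profile is concave annular
    st = full.final_state
    from sociowalk.metrics import socio_spatial_correlation

    assert socio_spatial_correlation(st.x, st.S) < -0.9


def test_snapshot_schedule_and_zero_length_run(small_params):
    times = log_snapshot_times(10_000, 30)
    assert times[0] == 0 and times[-1] == 10_000
    assert np.all(np.diff(times) > 0)

    p = small_params.replace(T=0)
    res = run(p, seed=1)
    assert list(res.series.ts) == [0]
    assert math.isnan(res.series.ssc[0])  # all ranks equal at t=0
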