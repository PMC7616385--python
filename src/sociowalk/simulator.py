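"""Simulation orchestration: initialisation, the event loop and recording.

A time step consists of (1) a move phase — every agent proposes a +-1 lattice
move, rejected at the walls of its own box potential; (2) an interaction
phase — every multiply-occupied site resolves one pairwise contest (sites in
ascending coordinate order); (3) a sensing phase — every agent independently
with probability r senses its neighbourhood, refits its belief and, subject
to the two-stage retention rule, re-solves its potential centre.

Retention (two-stage dynamics): before the waiting time t_c, new beliefs
with fidelity Phi < 0 are discarded and the previous belief and centre kept;
a failed sufficiency check always resets the belief to zero without moving
the centre; otherwise the belief is adopted and the centre updated.

Two equivalent implementations of the step are provided: a readable
pure-Python one (:func:`step`) built from the module-level operations, and a
compiled whole-run loop (:mod:`sociowalk._kernel`) used by :func:`run`.
Both consume the RNG stream identically, so trajectories match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernel, metrics, navigation, social
from .belief import Belief
from .params import SimParams


@dataclass(frozen=True)
class AgentState:
    """Read-only view of one agent: position, rank, belief, centre."""

    x: int
    S: float
    belief: Belief
    x_star: int
    fidelity: float


@dataclass
class PopulationState:
    """Array-of-agents state of one realisation at time ``t``."""

    t: int
    x: np.ndarray        # positions, int64
    S: np.ndarray        # social ranks, float64
    order: np.ndarray    # belief order per agent, int64 (0 = zero belief)
    b0: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    phi: np.ndarray      # last retained fidelity (NaN = undefined)
    xstar: np.ndarray    # potential centres, int64

    @property
    def N(self) -> int:
        return int(self.x.size)

    def agent(self, k: int) -> AgentState:
        b = Belief(
            order=int(self.order[k]),
            beta0=float(self.b0[k]),
            beta1=float(self.b1[k]),
            beta2=float(self.b2[k]),
            fidelity=float(self.phi[k]),
        )
        return AgentState(
            x=int(self.x[k]), S=float(self.S[k]), belief=b,
            x_star=int(self.xstar[k]), fidelity=float(self.phi[k]),
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            t=self.t,
            x=self.x.copy(), S=self.S.copy(), order=self.order.copy(),
            b0=self.b0.copy(), b1=self.b1.copy(), b2=self.b2.copy(),
            phi=self.phi.copy(), xstar=self.xstar.copy(),
        )


def initialise(params: SimParams, rng: np.random.Generator) -> PopulationState:
    """Draw the initial population.

    Positions are i.i.d. uniform on (-A0/2, A0/2), rounded to the nearest
    lattice site (halves away from zero); several agents may share a site.
    All ranks start at zero, beliefs are zero and each potential centre sits
    on its agent.
    """
    N = params.N
    half = params.A0 / 2.0
    cont = rng.uniform(-half, half, N)
    x = np.where(cont >= 0, np.floor(cont + 0.5), np.ceil(cont - 0.5)).astype(np.int64)
    return PopulationState(
        t=0,
        x=x,
        S=np.zeros(N),
        order=np.zeros(N, dtype=np.int64),
        b0=np.zeros(N),
        b1=np.zeros(N),
        b2=np.zeros(N),
        phi=np.full(N, np.nan),
        xstar=x.copy(),
    )


def step(state: PopulationState, params: SimParams,
         rng: np.random.Generator) -> PopulationState:
    """One event-loop step, in place (pure-Python reference implementation).

    Mirrors the compiled loop operation for operation; used for unit tests
    and exact-equivalence checks against the kernel.
    """
    N = state.N
    h, L = params.h, params.L
    x = state.x
    # -- move phase
    for k in range(N):
        x[k] = navigation.step(int(x[k]), int(state.xstar[k]), L, rng,
                               params.stay_prob)
    # -- interaction phase (sites ascending; ids within a site ascending)
    idx = np.argsort(x, kind="stable")
    i0 = 0
    while i0 < N:
        i1 = i0 + 1
        while i1 < N and x[idx[i1]] == x[idx[i0]]:
            i1 += 1
        if i1 - i0 >= 2:
            ids = [int(idx[i]) for i in range(i0, i1)]
            social.resolve_site(ids, state.S, params, rng)
        i0 = i1
    # -- sensing phase
    wmode = _kernel.W_TRICUBE if params.weights == "tricube" else _kernel.W_UNIFORM
    for k in range(N):
        if rng.random() < params.r:
            mask = np.abs(x - x[k]) <= h
            mask[k] = False
            us = (x[mask] - x[k]).astype(np.float64)
            ss = state.S[mask]
            ok, bo, c0, c1, c2, ph = _kernel.fit_sensed(us, ss, float(h), wmode)
            if not ok:
                state.order[k] = 0
                state.b0[k] = state.b1[k] = state.b2[k] = 0.0
                state.phi[k] = np.nan
            elif state.t < params.t_c and ph < 0.0:
                pass  # early low-fidelity measurement: not retained
            else:
                xk = int(x[k])
                state.order[k] = bo
                state.b0[k] = c0 - c1 * xk + c2 * xk * xk
                state.b1[k] = c1 - 2.0 * c2 * xk
                state.b2[k] = c2
                state.phi[k] = ph
                if params.center_rule == "window":
                    has, xs = _kernel.solve_center_windowed(
                        c0, c1, c2, bo, float(state.S[k]), np.int64(xk),
                        np.int64(h), rng
                    )
                else:
                    has, xs = _kernel.solve_center_centred(
                        c0, c1, c2, bo, float(state.S[k]), np.int64(xk), rng
                    )
                if has:
                    state.xstar[k] = xs
                    if params.center_rule != "frozen":
                        x[k] = navigation.handle_center_shift(
                            int(x[k]), int(xs), L
                        )
    state.t += 1
    return state


def log_snapshot_times(T: int, n: int = 60) -> np.ndarray:
    """Logarithmically spaced snapshot times in [0, T] (unique integers)."""
    if T < 1:
        return np.array([0], dtype=np.int64)
    ts = np.unique(np.geomspace(1, T, n).round().astype(np.int64))
    return np.concatenate(([0], ts))


@dataclass
class SimulationResult:
    """Output of one realisation: metric series and the final state."""

    params: SimParams
    series: "metrics.MetricsSeries"
    final_state: PopulationState
    snapshots: Optional[list[tuple[int, np.ndarray, np.ndarray]]] = None
    n_interactions: int = 0


def run(params: SimParams,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        snapshot_times: Optional[Sequence[int]] = None,
        record_snapshots: bool = False,
        use_kernel: bool = True) -> SimulationResult:
    """Run a full realisation of ``params.T`` steps.

    Metrics (mean nearest-neighbour distance, proportion of sensed
    neighbours, socio-spatial correlation) are recorded at
    ``snapshot_times`` (default: ~60 log-spaced times plus t = 0).  With
    ``record_snapshots`` the raw (t, positions, ranks) are kept as well.
    Identical (seed, params) produce identical outputs.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    state = initialise(params, rng)
    if snapshot_times is None:
        times = log_snapshot_times(params.T)
    else:
        times = np.unique(np.asarray(snapshot_times, dtype=np.int64))
        times = times[(times >= 0) & (times <= params.T)]
        if times.size == 0 or times[0] != 0:
            times = np.concatenate(([0], times))

    ts, deltas, nss, sscs = [], [], [], []
    snaps: Optional[list] = [] if record_snapshots else None

    def _record() -> None:
        ts.append(state.t)
        deltas.append(metrics.mean_nn_distance(state.x))
        nss.append(metrics.proportion_sensed(state.x, params.h))
        sscs.append(metrics.socio_spatial_correlation(state.x, state.S))
        if snaps is not None:
            snaps.append((state.t, state.x.copy(), state.S.copy()))

    wmode = _kernel.W_TRICUBE if params.weights == "tricube" else _kernel.W_UNIFORM
    pair_all = params.pair_mode == "all"
    crule = {"clamp": _kernel.CR_CLAMP, "window": _kernel.CR_WINDOW,
             "frozen": _kernel.CR_FROZEN}[params.center_rule]
    n_inter = 0
    _record()
    for t_next in times[1:]:
        n_steps = int(t_next - state.t)
        if use_kernel:
            n_inter += _kernel.advance(
                state.x, state.S, state.order,
                state.b0, state.b1, state.b2, state.phi, state.xstar,
                params.h, params.L, params.dS_max,
                params.delta_plus, params.delta_minus,
                params.r, params.t_c, params.stay_prob,
                wmode, pair_all, crule, state.t, n_steps, rng,
            )
            state.t += n_steps
        else:
            for _ in range(n_steps):
                step(state, params, rng)
        _record()

    series = metrics.MetricsSeries(
        ts=np.asarray(ts, dtype=np.int64),
        delta=np.asarray(deltas),
        ns=np.asarray(nss),
        ssc=np.asarray(sscs),
        ensemble=False,
    )
    return SimulationResult(params=params, series=series, final_state=state,
                            snapshots=snaps, n_interactions=n_inter)
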