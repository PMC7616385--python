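"""Ensembles, state-space sweeps, transient curves and synthetic fixtures.

The ensemble average <.> in the order parameters is taken over the
per-realisation metric values (mean of the Delta's, not Delta of pooled
positions).  Per-cell/per-realisation seeds are spawned deterministically
from the base seed via ``numpy.random.SeedSequence(base, spawn_key=...)``,
so sweeps are reproducible and cells are independent (parallelisable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, simulator
from .metrics import Regime
from .params import SimParams


def _cell_rng(base_seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=spawn_key)
    )


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_annular_fixture(N: int = 100,
                         alpha: float = 1.0,
                         m: float = 2.0,
                         K: float = 5.0,
                         rank_noise_sd: float = 0.0,
                         position_jitter: float = 0.0,
                         spacing: int = 1,
                         seed: Optional[int] = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic converged concave-annular configuration for metric tests.

    Agents sit at equispaced lattice sites recentred on 0 and carry ranks
    S = F(x; alpha, m, K) + Gaussian noise.  With zero noise the ranks are a
    strictly decreasing function of |x|, so the socio-spatial correlation of
    the configuration is exactly -1; increasing noise attenuates it.

    Returns ``(positions, ranks)``.
    """
    if N < 3:
        raise ValueError("fixture needs N >= 3")
    rng = np.random.default_rng(seed)
    offsets = (np.arange(N) - (N - 1) / 2.0) * spacing
    x = np.where(offsets >= 0, np.floor(offsets + 0.5),
                 np.ceil(offsets - 0.5)).astype(np.int64)
    if position_jitter > 0:
        x = x + np.rint(rng.normal(0.0, position_jitter, N)).astype(np.int64)
    # F is even; evaluating on |x| makes symmetric pairs tie bit-exactly
    ranks = metrics.shape_function(np.abs(x), alpha, m, K)
    if rank_noise_sd > 0:
        ranks = ranks + rng.normal(0.0, rank_noise_sd, N)
    return x, ranks


# ---------------------------------------------------------------------------
# transient (convergence) experiment


def transient_experiment(base_params: SimParams,
                         k_h_list: Sequence[float],
                         replicates: int = 10,
                         T: Optional[int] = None,
                         t_c: Optional[int] = None,
                         base_seed: int = 0,
                         n_snapshots: int = 60,
                         use_kernel: bool = True) -> pd.DataFrame:
    """Ensemble socio-spatial correlation curves C(t) for several k_h.

    Runs ``replicates`` realisations per sensory-radius scaling and returns
    a tidy table (t, k_h, mean_ssc, sd_ssc, n) where n counts realisations
    with a defined SSC at that snapshot (the SSC is undefined while all
    ranks are still equal).  Larger k_h should reach any fixed negative SSC
    threshold earlier.
    """
    rows = []
    for ih, k_h in enumerate(k_h_list):
        p = base_params.replace(k_h=float(k_h))
        if T is not None:
            p = p.replace(T=int(T))
        if t_c is not None:
            p = p.replace(t_c=int(t_c))
        times = simulator.log_snapshot_times(p.T, n_snapshots)
        curves = np.empty((replicates, times.size))
        for rep in range(replicates):
            rng = _cell_rng(base_seed, ih, rep)
            res = simulator.run(p, rng=rng, snapshot_times=times,
                                use_kernel=use_kernel)
            curves[rep] = res.series.ssc
        n_def = np.sum(~np.isnan(curves), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(curves, axis=0)
            sd = np.nanstd(curves, axis=0, ddof=1)
        for i, t in enumerate(times):
            rows.append(
                {"t": int(t), "k_h": float(k_h),
                 "mean_ssc": float(mean[i]) if n_def[i] else np.nan,
                 "sd_ssc": float(sd[i]) if n_def[i] > 1 else np.nan,
                 "n": int(n_def[i])}
            )
    return pd.DataFrame(rows)


def crossing_time(df: pd.DataFrame, k_h: float,
                  threshold: float = -0.5) -> Optional[int]:
    """Earliest snapshot time at which the ensemble mean SSC <= threshold."""
    sub = df[(df.k_h == k_h) & (df.mean_ssc <= threshold)]
    return None if sub.empty else int(sub.t.min())


# ---------------------------------------------------------------------------
# state-space sweep


@dataclass
class SweepSpec:
    """Grid specification for a (k_L, k_h) state-space sweep."""

    k_L: Sequence[float]
    k_h: Sequence[float]
    replicates: int = 10
    T: int = 1_000_000
    t_c: int = 3_000
    base_seed: int = 0
    n_snapshots: int = 60
    tail_snapshots: int = 5   # final-time metrics average the last few snaps
    desk_scale: bool = True


def paper_sweep_spec() -> SweepSpec:
    """Full-horizon sweep over the reference grids (paper mode).

    L in {5, 10, ..., 120} and h in {250, 500, 1000, 1500, ..., 8000} at
    rho0 = 0.05, N = 100, i.e. k_L in {0.25, ..., 6} and k_h in
    {0.125, 0.25, 0.5, 0.75, ..., 4}, with T = 1e9 and t_c = 3e6.  At these
    horizons a sweep takes cluster-scale compute; expected outcomes are a
    sharp Full/Partial Sensing transition (J ~ 0 vs J of order 1-10,
    n_s = 1 vs n_s in [0.2, 0.4]) and an Unstable region at small k_h where
    2h/Delta falls below ~6.
    """
    L_grid = np.arange(5, 125, 5)
    h_grid = np.concatenate(([250], np.arange(500, 8500, 500)))
    rho0, N = 0.05, 100
    return SweepSpec(
        k_L=(L_grid * rho0).tolist(),
        k_h=(h_grid * rho0 / N).tolist(),
        replicates=10,
        T=10**9,
        t_c=3 * 10**6,
        desk_scale=False,
    )


def desk_sweep_spec(T: int = 1_000_000) -> SweepSpec:
    """Scaled-down sweep preset (coarse grid, reduced horizon).

    t_c is scaled in proportion to the reduced horizon (t_c = 3e6 * T/1e9),
    mirroring how the waiting time relates to the full-length runs.  This is
    NOT the full-horizon protocol; long-time regime boundaries shift at
    short T.
    """
    t_c = max(1, int(round(3e6 * T / 1e9)))
    return SweepSpec(
        k_L=[0.5, 1.0, 2.0],
        k_h=[0.3, 1.0],
        replicates=5,
        T=T,
        t_c=t_c,
        desk_scale=True,
    )


def _cell_filename(iL: int, ih: int) -> str:
    return f"cell_{iL:03d}_{ih:03d}.json"


def _run_cell(spec: SweepSpec, base_params: SimParams, iL: int, ih: int
              ) -> dict:
    k_L = float(spec.k_L[iL])
    k_h = float(spec.k_h[ih])
    p = base_params.replace(k_L=k_L, k_h=k_h, T=spec.T, t_c=spec.t_c)
    times = simulator.log_snapshot_times(p.T, spec.n_snapshots)
    deltas = np.empty((spec.replicates, times.size))
    nss = np.empty_like(deltas)
    sscs = np.empty_like(deltas)
    pooled_x: list[np.ndarray] = []
    pooled_S: list[np.ndarray] = []
    for rep in range(spec.replicates):
        rng = _cell_rng(spec.base_seed, iL, ih, rep)
        res = simulator.run(p, rng=rng, snapshot_times=times)
        deltas[rep] = res.series.delta
        nss[rep] = res.series.ns
        sscs[rep] = res.series.ssc
        fx = res.final_state.x
        pooled_x.append(fx - fx.mean())
        pooled_S.append(res.final_state.S)

    ens_delta = deltas.mean(axis=0)
    ens_ns = nss.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ens_ssc = np.nanmean(sscs, axis=0)
        tail = slice(-spec.tail_snapshots, None)
        ssc_f = float(np.nanmean(ens_ssc[tail]))
    delta_f = float(ens_delta[tail].mean())
    ns_f = float(ens_ns[tail].mean())
    stationary, t_onset = metrics.detect_stationarity(times, ens_delta)
    mean_sensed = 2.0 * p.h / delta_f if delta_f > 0 else np.inf
    regime = metrics.classify_regime(ns_f, mean_sensed, stationary)

    row = {
        "iL": iL, "ih": ih, "k_L": k_L, "k_h": k_h,
        "h": p.h, "L": p.L, "occupation_length": 2 * p.L - 1,
        "delta": delta_f, "ns": ns_f, "ssc": ssc_f,
        "mean_sensed": float(mean_sensed),
        "stationary": bool(stationary),
        "t_onset": t_onset if t_onset is None else float(t_onset),
        "regime": regime.value,
        "n_reps": spec.replicates,
        "error": "",
    }
    try:
        fit = metrics.fit_shape(np.concatenate(pooled_x),
                                np.concatenate(pooled_S))
        row.update(alpha=fit.alpha, m=fit.m, K=fit.K, J=fit.J,
                   fit_residual=fit.residual)
    except (ValueError, RuntimeError) as exc:  # degenerate profile
        row.update(alpha=np.nan, m=np.nan, K=np.nan, J=np.nan,
                   fit_residual=np.nan)
        row["error"] = f"shape fit failed: {exc}"
    return row


def run_sweep(spec: SweepSpec,
              base_params: Optional[SimParams] = None,
              cache_dir: Optional[str | Path] = None,
              jobs: int = 1) -> pd.DataFrame:
    """Run the (k_L, k_h) sweep and aggregate per-cell ensemble metrics.

    Each cell runs ``spec.replicates`` realisations, averages the order
    parameters over the ensemble, takes final values as the mean over the
    last ``tail_snapshots`` snapshots, fits the shape function to the pooled
    final configurations and classifies the regime.  With ``cache_dir`` set,
    finished cells are written as JSON manifests and re-used on resume;
    re-running a cached sweep reproduces the result table byte-for-byte.
    Per-cell failures are recorded in the ``error`` column and the sweep
    continues.
    """
    if base_params is None:
        base_params = SimParams(k_h=1.0, k_L=1.0)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    cells = [(iL, ih) for iL in range(len(spec.k_L))
             for ih in range(len(spec.k_h))]

    def _one(iL: int, ih: int) -> dict:
        if cache is not None:
            f = cache / _cell_filename(iL, ih)
            if f.exists():
                return json.loads(f.read_text())
        try:
            row = _run_cell(spec, base_params, iL, ih)
        except Exception as exc:  # record and continue
            row = {"iL": iL, "ih": ih,
                   "k_L": float(spec.k_L[iL]), "k_h": float(spec.k_h[ih]),
                   "error": repr(exc)}
        row = dict(sorted(row.items()))  # canonical key order (cache-stable)
        if cache is not None:
            (cache / _cell_filename(iL, ih)).write_text(
                json.dumps(row, sort_keys=True) + "\n"
            )
        return row

    if jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=jobs)(delayed(_one)(iL, ih) for iL, ih in cells)
    else:
        rows = [_one(iL, ih) for iL, ih in cells]
    return pd.DataFrame(rows)
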