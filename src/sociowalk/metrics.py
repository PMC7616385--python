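"""Order parameters, macroscopic shape fits and regime classification.

Per-realisation order parameters (the ensemble average over realisations is
applied by the caller, e.g. :mod:`sociowalk.experiments`):

* mean nearest-neighbour distance
      Delta = (1/N) sum_j min_{k != j} |x_j - x_k|
  — the cohesion/dispersion measure; stationarity of the system is judged
  by Delta(t) converging to a constant;

* proportion of sensed neighbours
      n_s = (1/(N(N-1))) sum_j sum_{k != j} 1(|x_j - x_k| <= h)  in [0, 1];

* socio-spatial correlation (SSC)
      C = Corr(|x_k - xbar|, S_k)  in [-1, 1]
  with Corr the tie-corrected Spearman rank correlation and xbar the group
  centre of mass; C = -1 is the perfect concave annular state.

The mesoscopic rank profile S(x) is summarised by the integrated-sigmoid
shape function

    F(x; alpha, m, K) = -(2m/alpha) ln(1 + exp(-alpha x)) - m x + K,

a concave even function interpolating between a quadratic (shape parameter
J = K alpha / m - ln 4 near 0) and the tent K - m|x| (large J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class MetricsSeries:
    """Time series of the three order parameters for one run or ensemble."""

    ts: np.ndarray
    delta: np.ndarray
    ns: np.ndarray
    ssc: np.ndarray
    ensemble: bool = False

    def __post_init__(self) -> None:
        n = len(self.ts)
        if not (len(self.delta) == len(self.ns) == len(self.ssc) == n):
            raise ValueError("all series must have the same length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.ts, "delta": self.delta, "ns": self.ns, "ssc": self.ssc}
        )


def mean_nn_distance(positions: np.ndarray) -> float:
    """Mean over agents of the distance to the nearest other agent.

    Translation- and reflection-invariant; zero distances from co-located
    agents count as zero.  Requires at least two agents.
    """
    x = np.sort(np.asarray(positions, dtype=np.float64))
    if x.size < 2:
        raise ValueError("mean nearest-neighbour distance needs N >= 2")
    gaps = np.diff(x)
    left = np.concatenate(([np.inf], gaps))
    right = np.concatenate((gaps, [np.inf]))
    return float(np.minimum(left, right).mean())


def proportion_sensed(positions: np.ndarray, h: float) -> float:
    """Fraction of ordered pairs within sensing distance h (boundary inclusive)."""
    x = np.asarray(positions, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("proportion of sensed neighbours needs N >= 2")
    if h < 0:
        raise ValueError("h must be non-negative")
    within = np.abs(x[:, None] - x[None, :]) <= h
    np.fill_diagonal(within, False)
    return float(within.sum() / (n * (n - 1)))


def socio_spatial_correlation(positions: np.ndarray,
                              ranks: np.ndarray) -> float:
    """Spearman correlation between radial distance from the centre of mass
    and social rank.

    Tie-corrected (Pearson correlation of average-ranked data).  Returns NaN
    when either variable has zero variance (e.g. all ranks equal), flagging
    the value as undefined.
    """
    x = np.asarray(positions, dtype=np.float64)
    s = np.asarray(ranks, dtype=np.float64)
    if x.size < 3:
        raise ValueError("socio-spatial correlation needs N >= 3")
    radial = np.abs(x - x.mean())
    if np.all(radial == radial[0]) or np.all(s == s[0]):
        return math.nan
    rho = stats.spearmanr(radial, s).statistic
    return float(rho)


def shape_function(x, alpha: float, m: float, K: float) -> np.ndarray:
    """Integrated-sigmoid shape function F(x; alpha, m, K).

    Evaluated in log-sum-exp form, so it neither overflows nor loses the
    tails for |alpha x| up to ~1e6.
    """
    x = np.asarray(x, dtype=np.float64)
    return -(2.0 * m / alpha) * np.logaddexp(0.0, -alpha * x) - m * x + K


@dataclass(frozen=True)
class ShapeFit:
    """Fitted shape-function parameters (all positive) and fit quality.

    The shape parameter J is always recomputed from (alpha, m, K), never
    stored, so it cannot drift out of sync.
    """

    alpha: float
    m: float
    K: float
    residual: float
    success: bool = True
    n_points: int = 0

    @property
    def J(self) -> float:
        return self.K * self.alpha / self.m - math.log(4.0)


def fit_shape(x: np.ndarray, S: np.ndarray, recentre: bool = True) -> ShapeFit:
    """Nonlinear least-squares fit of the shape function to a rank profile.

    ``x, S`` are pooled agent configurations (positions are recentred on
    their mean unless ``recentre=False``).  Initialisation: K from the
    profile maximum, m from the outer-edge slope, alpha by a coarse
    geometric grid in which (m, K) are profiled out linearly — among grid
    points within 1% of the best misfit the smallest alpha is preferred
    (the smoothest shape consistent with the data).  The final polish is a
    Levenberg-Marquardt solve in log-parameters, which enforces
    alpha, m, K > 0.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    S = np.asarray(S, dtype=np.float64).ravel()
    if x.size != S.size or x.size < 10:
        raise ValueError("shape fit needs at least 10 (x, S) points")
    if recentre:
        x = x - x.mean()

    # coarse grid on alpha; F = m * g(x; alpha) + K is linear in (m, K)
    best: Optional[tuple[float, float, float, float]] = None  # sse, a, m, K
    candidates: list[tuple[float, float, float, float]] = []
    for a in np.geomspace(1e-4, 1e3, 57):
        g = -(2.0 / a) * np.logaddexp(0.0, -a * x) - x
        A = np.column_stack((g, np.ones_like(g)))
        coef, *_ = np.linalg.lstsq(A, S, rcond=None)
        m0, K0 = float(coef[0]), float(coef[1])
        if m0 <= 0 or K0 <= 0:
            continue
        resid = A @ coef - S
        candidates.append((float(resid @ resid), a, m0, K0))
    if candidates:
        sse_min = min(c[0] for c in candidates)
        # smallest alpha among near-optimal grid points
        tol = sse_min * 1.01 + 1e-12
        best = min((c for c in candidates if c[0] <= tol), key=lambda c: c[1])
        _, a0, m0, K0 = best
    else:  # fall back to heuristics on degenerate profiles
        a0, m0, K0 = 1.0, 1.0, max(float(S.max()), 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, m, K = np.exp(np.clip(theta, -50.0, 50.0))
        return shape_function(x, a, m, K) - S

    sol = optimize.least_squares(
        residuals, x0=np.log([a0, m0, K0]), method="lm", max_nfev=2000
    )
    alpha, m, K = (float(v) for v in np.exp(np.clip(sol.x, -50.0, 50.0)))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return ShapeFit(alpha=alpha, m=m, K=K, residual=rms,
                    success=bool(sol.success), n_points=x.size)


def detect_stationarity(ts: Sequence[float], delta: Sequence[float],
                        rel_tol: float = 0.05,
                        min_snapshots: int = 20) -> tuple[bool, Optional[float]]:
    """Declare stationarity when Delta(t) has stopped drifting.

    At each snapshot time t the means of Delta over the trailing half-decade
    windows (t/10, t/sqrt(10)] and (t/sqrt(10), t] are compared; the series
    is stationary at t when their relative difference is below ``rel_tol``.
    Returns ``(is_stationary, t_onset)`` where the onset is the earliest
    time from which the criterion holds through to the end.
    """
    ts = np.asarray(ts, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    if ts.size < min_snapshots:
        return False, None
    sqrt10 = math.sqrt(10.0)
    ok = np.zeros(ts.size, dtype=bool)
    for i, t in enumerate(ts):
        if t <= 0:
            continue
        w_new = delta[(ts > t / sqrt10) & (ts <= t)]
        w_old = delta[(ts > t / 10.0) & (ts <= t / sqrt10)]
        if w_new.size < 3 or w_old.size < 3:
            continue
        m_new, m_old = w_new.mean(), w_old.mean()
        ok[i] = abs(m_new - m_old) <= rel_tol * max(abs(m_old), 1e-12)
    if not ok[-1]:
        return False, None
    onset_idx = ts.size - 1
    while onset_idx > 0 and ok[onset_idx - 1]:
        onset_idx -= 1
    return True, float(ts[onset_idx])


class Regime(str, Enum):
    """Long-time regime of the system in (k_L, k_h) space."""

    FULL_SENSING = "FullSensing"
    PARTIAL_SENSING = "PartialSensing"
    UNSTABLE = "Unstable"


# n_s threshold for the Full Sensing label; slightly below 1 to tolerate
# single-snapshot fluctuation.
FULL_SENSING_NS = 0.999
# systems whose estimated mean number of sensed neighbours 2h/Delta drops
# below this are dispersing
UNSTABLE_MEAN_SENSED = 6.0


def classify_regime(ns_final: float, mean_sensed: float,
                    stationary: bool = True) -> Regime:
    """Classify the long-time state from its final order parameters.

    ``mean_sensed`` is the estimated mean number of sensed neighbours,
    2h / Delta(t).  Unstable when that falls below 6 or no stationary state
    was reached; Full Sensing when essentially every ordered pair is within
    sensing range (n_s >= 0.999); Partial Sensing otherwise.
    """
    if not stationary or mean_sensed < UNSTABLE_MEAN_SENSED:
        return Regime.UNSTABLE
    if ns_final >= FULL_SENSING_NS:
        return Regime.FULL_SENSING
    return Regime.PARTIAL_SENSING
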