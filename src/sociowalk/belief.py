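"""Sensing, regression beliefs, model fidelity and the potential-centre solve.

An agent k senses the positions and social ranks of all neighbours within
its communication radius h and summarises them with a weighted polynomial
regression belief

    S_hat_k(x) = beta0 + beta1 x + beta2 x**2       (order 2)

falling back to the first-order form whenever the quadratic fit measures a
minimum (beta2 > 0), so that retained beliefs always have a single maximum.
Each belief carries a model fidelity

    Phi_k = 1 - SS_res / SS_tot   in (-inf, 1]

(the coefficient of determination of the fit on the sensed data).  The
potential centre x* is the lattice site at which the belief predicts the
agent's own rank should reside,

    x* = argmin_x | S_k - S_hat_k(x) |,

rounded to the nearest integer (halves away from zero).

Fits are performed internally in sensor-centred, scaled coordinates for
conditioning; coefficients are stored in absolute lattice coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from ._kernel import COND_LIMIT  # noqa: F401  (re-exported for documentation)


class InsufficientDataError(ValueError):
    """Sensed data is of insufficient quantity or quality for the fit."""


@dataclass(frozen=True)
class SensedData:
    """Positions and ranks of the neighbours sensed by one agent.

    The sensing agent itself is excluded; all positions satisfy
    |x - sensor_x| <= h (closed ball).
    """

    xs: np.ndarray
    Ss: np.ndarray
    sensor_x: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "xs", np.asarray(self.xs, dtype=np.float64))
        object.__setattr__(self, "Ss", np.asarray(self.Ss, dtype=np.float64))
        if self.xs.shape != self.Ss.shape:
            raise ValueError("xs and Ss must have the same shape")

    @property
    def n(self) -> int:
        return int(self.xs.size)

    @property
    def offsets(self) -> np.ndarray:
        """Neighbour positions relative to the sensor."""
        return self.xs - self.sensor_x


@dataclass(frozen=True)
class Belief:
    """Polynomial belief of one agent.

    ``order`` 0 encodes the reset state S_hat(x) = 0 (all coefficients zero,
    fidelity undefined/NaN).  Coefficients are in absolute lattice
    coordinates.  A raw order-2 fit may measure a minimum (beta2 > 0); the
    update logic in :func:`belief_update` then refits at order 1, so beliefs
    actually retained by agents never have beta2 > 0.
    """

    order: int
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    fidelity: float = field(default=math.nan)
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"order must be 0, 1 or 2, got {self.order!r}")
        if self.order == 0 and (self.beta0 or self.beta1 or self.beta2):
            raise ValueError("zero belief must have zero coefficients")
        if not math.isnan(self.fidelity) and self.fidelity > 1.0:
            raise ValueError("fidelity cannot exceed 1")

    @classmethod
    def zero(cls) -> "Belief":
        return cls(order=0)

    @property
    def is_zero(self) -> bool:
        return self.order == 0

    def predict(self, x) -> np.ndarray:
        """Evaluate S_hat(x) at lattice coordinates ``x``."""
        x = np.asarray(x, dtype=np.float64)
        return self.beta0 + self.beta1 * x + self.beta2 * x * x


def sense(k: int, positions: np.ndarray, ranks: np.ndarray, h: int) -> SensedData:
    """Collect the neighbours of agent ``k`` within the closed ball of radius h.

    Returns the (possibly empty) sensed dataset; the sensing agent itself is
    excluded even when co-located with neighbours.
    """
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h!r}")
    positions = np.asarray(positions)
    ranks = np.asarray(ranks)
    mask = np.abs(positions - positions[k]) <= h
    mask[k] = False
    return SensedData(positions[mask], ranks[mask], sensor_x=int(positions[k]))


def tricube_weights(data: SensedData, h: int) -> np.ndarray:
    """Distance-decay kernel w = (1 - (|dx|/h)^3)^3 on the sensed offsets."""
    z = np.minimum(np.abs(data.offsets) / h, 1.0)
    return (1.0 - z**3) ** 3


def _check_solvable(data: SensedData, order: int) -> None:
    # minimal identifiability for a raw fit; belief_update applies the
    # stricter sufficiency rule (order + 2 points) on top of this
    if data.n < order + 1:
        raise InsufficientDataError(
            f"order-{order} fit needs at least {order + 1} neighbours, "
            f"got {data.n}"
        )
    if np.unique(data.offsets).size < order + 1:
        raise InsufficientDataError(
            f"order-{order} fit needs neighbours at >= {order + 1} distinct "
            "positions"
        )


def fit_polynomial(data: SensedData, order: int,
                   weights: Optional[np.ndarray] = None) -> Belief:
    """Weighted least-squares polynomial fit of the sensed data.

    Minimises sum_j w_j (S_j - p(x_j))**2 for p of degree ``order`` in
    {1, 2}.  Coordinates are centred on the sensor and scaled internally;
    the returned coefficients are absolute.  Fidelity is not filled in here
    (see :func:`model_fidelity`).

    Raises
    ------
    InsufficientDataError
        On too few points, too few distinct positions, or a numerically
        degenerate design.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order!r}")
    _check_solvable(data, order)
    u = data.offsets
    scale = max(1.0, float(np.max(np.abs(u))))
    if weights is None:
        w = np.ones(data.n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != u.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per neighbour")
    ok, c0, c1, c2 = _kernel.wls_polyfit_scaled(u / scale, data.Ss, w, order)
    if not ok:
        raise InsufficientDataError("singular or ill-conditioned design matrix")
    c1 /= scale
    c2 /= scale * scale
    xk = data.sensor_x
    return Belief(
        order=order,
        beta0=c0 - c1 * xk + c2 * xk * xk,
        beta1=c1 - 2.0 * c2 * xk,
        beta2=c2,
        n_points=data.n,
    )


def model_fidelity(data: SensedData, belief: Belief) -> float:
    """Model fidelity Phi = 1 - SS_res / SS_tot of a belief on sensed data.

    SS_tot is taken about the mean sensed rank.  When the sensed ranks have
    zero variance the ratio is undefined; the convention is Phi = 1 for a
    zero-residual fit and Phi = -inf otherwise (ordered below every finite
    fidelity, so it funnels into the low-fidelity handling downstream).
    """
    if data.n < 2:
        raise ValueError("model fidelity needs at least 2 sensed neighbours")
    resid = data.Ss - belief.predict(data.xs)
    ss_res = float(resid @ resid)
    dev = data.Ss - data.Ss.mean()
    ss_tot = float(dev @ dev)
    if ss_tot == 0.0:
        sbar = float(data.Ss.mean())
        return 1.0 if ss_res <= 1e-12 * (1.0 + sbar * sbar) else -math.inf
    return 1.0 - ss_res / ss_tot


def belief_update(data: SensedData, params=None, *,
                  weights: str = "uniform", h: Optional[int] = None
                  ) -> tuple[Belief, bool]:
    """Full belief computation for one sensing event.

    Order of operations: sufficiency check (fail -> zero belief, centre not
    updated); order-2 fit; fallback to order 1 whenever a minimum is
    measured (beta2 > 0); fidelity of the retained fit.

    ``params`` may be a :class:`~sociowalk.params.SimParams` supplying the
    ``weights`` mode and ``h`` (needed for tricube weights).

    Returns ``(belief, center_update_allowed)``.
    """
    if params is not None:
        weights = params.weights
        h = params.h
    wmode = _kernel.W_TRICUBE if weights == "tricube" else _kernel.W_UNIFORM
    if wmode == _kernel.W_TRICUBE and h is None:
        raise ValueError("tricube weights require the sensory radius h")
    ok, order, c0, c1, c2, phi = _kernel.fit_sensed(
        np.ascontiguousarray(data.offsets, dtype=np.float64),
        np.ascontiguousarray(data.Ss, dtype=np.float64),
        float(h) if h is not None else 1.0,
        wmode,
    )
    if not ok:
        return Belief.zero(), False
    xk = data.sensor_x
    return (
        Belief(
            order=int(order),
            beta0=c0 - c1 * xk + c2 * xk * xk,
            beta1=c1 - 2.0 * c2 * xk,
            beta2=c2,
            fidelity=float(phi),
            n_points=data.n,
        ),
        True,
    )


def solve_potential_center(S_k: float, belief: Belief, x_k: int,
                           rng: Optional[np.random.Generator] = None
                           ) -> Optional[int]:
    """Solve x* = argmin_x |S_k - S_hat(x)| for a non-zero belief.

    For a concave quadratic belief, the minimiser is the root of
    S_hat(x) = S_k nearer the agent's current position when S_k is below the
    belief maximum (exact ties between the two roots broken uniformly at
    random), and the vertex otherwise.  For a linear belief it is the exact
    inversion.  The result is rounded half away from zero.

    Returns ``None`` for a degenerate (flat) belief — the centre must then
    not be updated.
    """
    if belief.is_zero:
        raise ValueError("cannot solve the potential centre of a zero belief")
    if rng is None:
        rng = np.random.default_rng(0)
    # re-centre the absolute coefficients on the agent
    c2 = belief.beta2
    c1 = belief.beta1 + 2.0 * c2 * x_k
    c0 = belief.beta0 + belief.beta1 * x_k + c2 * x_k * x_k
    has, xs = _kernel.solve_center_centred(
        c0, c1, c2, belief.order, float(S_k), np.int64(x_k), rng
    )
    return int(xs) if has else None
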