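"""Lattice random-walk motion under an individual box potential.

Each agent is confined by an infinite-wall box potential V(x; x*, L) that is
zero on the open interval |x - x*| < L (2L - 1 permitted sites) and infinite
elsewhere.  Moves are +-1 proposals with equal probability, rejected when
they would enter a forbidden site, so an agent performs a reflected simple
random walk inside its own box.
"""

from __future__ import annotations

import math

import numpy as np


def potential(x: int, center: int, L: int) -> float:
    """Box potential value at site ``x``: 0.0 inside, ``math.inf`` outside."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L!r}")
    return 0.0 if abs(x - center) < L else math.inf


def is_permitted(x: int, center: int, L: int) -> bool:
    """True iff site ``x`` lies strictly inside the box (|x - center| < L)."""
    return abs(x - center) < L


def step(x: int, center: int, L: int, rng: np.random.Generator,
         stay_prob: float = 0.0) -> int:
    """One walk update: propose x +- 1, reject at the walls.

    With ``stay_prob > 0`` the walk is lazy (the agent stays put with that
    probability before proposing).  The returned site is always permitted,
    assuming the input site is.
    """
    if stay_prob > 0.0:
        if rng.random() < stay_prob:
            return x
    d = 1 if rng.random() < 0.5 else -1
    nx = x + d
    return nx if abs(nx - center) < L else x


def handle_center_shift(x: int, new_center: int, L: int) -> int:
    """Re-admit an agent stranded by a moved potential centre.

    If ``x`` is still inside the new box it is unchanged; otherwise it is
    clamped to the nearest permitted site, ``new_center +- (L - 1)``.
    """
    if abs(x - new_center) < L:
        return x
    return new_center - (L - 1) if x < new_center else new_center + (L - 1)
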