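"""Model parameters, validation and lattice scalings.

The model has two natural parameterisations of its spatial scales: the raw
lattice radii ``h`` (sensory radius) and ``L`` (box-potential radius), or the
density-relative scalings ``k_h`` and ``k_L`` with

    h = k_h * N / rho0        L = k_L / rho0

where ``rho0`` is the initial agent density (agents per lattice site) and
``N`` the number of agents.  ``k_h = 1`` means a centrally placed agent
initially senses the whole group in each radial direction; ``k_L = 1`` gives
an expected full overlap between the box potentials of neighbouring agents at
t = 0.  Both directions are supported: give either the k's or the radii.

The initial positions are drawn from a uniform interval of width
``A0 = N / rho0`` lattice sites.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any


def round_half_away(v: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return math.floor(v + 0.5) if v >= 0 else math.ceil(v - 0.5)


def derive_lattice_params(
    k_h: float, k_L: float, N: int, rho0: float
) -> tuple[int, int, float]:
    """Translate dimensionless scalings into lattice radii.

    Returns ``(h, L, A0)`` with ``h = round(k_h N / rho0)``,
    ``L = round(k_L / rho0)`` (both at least 1, rounded half away from zero)
    and ``A0 = N / rho0``, the width of the initial placement interval.

    Raises
    ------
    ValueError
        If any input is non-positive or ``N`` is not an integer.
    """
    if N != int(N) or N <= 0:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    if k_h <= 0 or k_L <= 0 or rho0 <= 0:
        raise ValueError(
            f"k_h, k_L and rho0 must be positive, got {k_h!r}, {k_L!r}, {rho0!r}"
        )
    h = max(1, round_half_away(k_h * N / rho0))
    L = max(1, round_half_away(k_L / rho0))
    return h, L, N / rho0


_WEIGHT_MODES = ("uniform", "tricube")
_PAIR_MODES = ("single", "all")
_CENTER_RULES = ("clamp", "window", "frozen")


@dataclass
class SimParams:
    """All model constants and scalings for one simulation.

    Defaults are the reference parameter set: N = 100 agents at initial
    density rho0 = 0.05, social interaction threshold dS_max = 100, sensing
    probability r = 0.01 per agent per step, winner/loser rank updates
    (delta_plus, delta_minus) = (1, 0), and measurement waiting time
    t_c = 3e6 steps.  Shorter runs should scale ``t_c`` with ``T``
    proportionally (this is deliberate and not automatic).

    Exactly one of (``k_h``, ``h``) and one of (``k_L``, ``L``) must be
    supplied (giving both is allowed only when consistent); the missing one
    is derived at construction.
    """

    N: int = 100
    rho0: float = 0.05
    k_h: float | None = None
    k_L: float | None = None
    h: int | None = None
    L: int | None = None
    dS_max: float = 100.0
    delta_plus: float = 1.0
    delta_minus: float = 0.0
    r: float = 0.01
    t_c: int = 3_000_000
    T: int = 1_000_000
    seed: int = 0
    weights: str = "uniform"     # regression weights: "uniform" | "tricube"
    pair_mode: str = "all"       # co-location pairing: "all" | "single"
    stay_prob: float = 0.0       # lazy-walk stay probability
    center_rule: str = "window"  # x* update rule: "window" | "clamp" | "frozen"

    def __post_init__(self) -> None:
        if self.N != int(self.N) or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        self.N = int(self.N)
        for name in ("rho0", "dS_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r!r}")
        if not 0.0 <= self.stay_prob < 1.0:
            raise ValueError(f"stay_prob must lie in [0, 1), got {self.stay_prob!r}")
        if self.delta_plus < 0 or self.delta_minus < 0:
            raise ValueError("delta_plus and delta_minus must be non-negative")
        if self.T < 0 or self.t_c < 0:
            raise ValueError("T and t_c must be non-negative")
        if self.weights not in _WEIGHT_MODES:
            raise ValueError(f"weights must be one of {_WEIGHT_MODES}")
        if self.pair_mode not in _PAIR_MODES:
            raise ValueError(f"pair_mode must be one of {_PAIR_MODES}")
        if self.center_rule not in _CENTER_RULES:
            raise ValueError(f"center_rule must be one of {_CENTER_RULES}")

        # Resolve the (k_h, h) pair.
        if self.h is None:
            if self.k_h is None:
                raise ValueError("one of k_h or h must be given")
            self.h = max(1, round_half_away(self.k_h * self.N / self.rho0))
        else:
            if self.h < 1 or self.h != int(self.h):
                raise ValueError(f"h must be an integer >= 1, got {self.h!r}")
            self.h = int(self.h)
            if self.k_h is None:
                self.k_h = self.h * self.rho0 / self.N
            elif max(1, round_half_away(self.k_h * self.N / self.rho0)) != self.h:
                raise ValueError(
                    f"inconsistent k_h={self.k_h!r} and h={self.h!r} "
                    f"for N={self.N}, rho0={self.rho0}"
                )
        # Resolve the (k_L, L) pair.
        if self.L is None:
            if self.k_L is None:
                raise ValueError("one of k_L or L must be given")
            self.L = max(1, round_half_away(self.k_L / self.rho0))
        else:
            if self.L < 1 or self.L != int(self.L):
                raise ValueError(f"L must be an integer >= 1, got {self.L!r}")
            self.L = int(self.L)
            if self.k_L is None:
                self.k_L = self.L * self.rho0
            elif max(1, round_half_away(self.k_L / self.rho0)) != self.L:
                raise ValueError(
                    f"inconsistent k_L={self.k_L!r} and L={self.L!r} "
                    f"for rho0={self.rho0}"
                )
        if self.k_h <= 0 or self.k_L <= 0:
            raise ValueError("k_h and k_L must be positive")

    @property
    def A0(self) -> float:
        """Width of the initial placement interval, N / rho0 lattice sites."""
        return self.N / self.rho0

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with fields changed; derived radii are recomputed.

        Changing ``k_h``/``k_L``/``N``/``rho0`` drops the stored ``h``/``L``
        (unless explicitly passed) so they are re-derived consistently.
        """
        d = dataclasses.asdict(self)
        if any(k in changes for k in ("k_h", "N", "rho0")) and "h" not in changes:
            d["h"] = None
        if any(k in changes for k in ("k_L", "rho0")) and "L" not in changes:
            d["L"] = None
        if "h" in changes and "k_h" not in changes:
            d["k_h"] = None
        if "L" in changes and "k_L" not in changes:
            d["k_L"] = None
        d.update(changes)
        return SimParams(**d)

    def as_dict(self) -> dict[str, Any]:
        """Fully resolved parameter record (includes derived h, L, A0)."""
        d = dataclasses.asdict(self)
        d["A0"] = self.A0
        return d

    def to_json(self, path: str | Path) -> None:
        """Write the resolved-parameters manifest alongside run outputs."""
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "SimParams":
        """Load parameters from a flat TOML file; unknown keys are rejected.

        Keyword ``overrides`` (e.g. from CLI flags) take precedence over the
        file values.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown parameter keys in {path}: {unknown}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
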