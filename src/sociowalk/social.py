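"""Pairwise dominance interactions between co-located agents.

Contest dynamics follow the Bonabeau-type scheme with two stabilising
modifications: a hard interaction gate (agents only interact while their
rank difference is strictly below the threshold dS_max) and a deterministic
outcome rule (the higher-ranked agent always wins; exact ties are decided by
a fair coin).  The winner's rank increases by delta_plus and the loser's
decreases by delta_minus (floored at zero); with the default (1, 0) ranks
are non-decreasing and there is no relaxation towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._kernel import randint_below


@dataclass(frozen=True)
class InteractionResult:
    """Record of one attempted interaction between agents ``j`` and ``k``.

    ``occurred`` is False when the gate blocked the contest (rank difference
    at or above the threshold); ``winner``/``loser`` are set only when it
    occurred.
    """

    j: int
    k: int
    occurred: bool
    winner: Optional[int] = None
    loser: Optional[int] = None
    site: Optional[int] = None

    def __post_init__(self) -> None:
        if self.occurred and self.winner == self.loser:
            raise ValueError("winner and loser must differ for a realised contest")


def interaction_gate(S_j: float, S_k: float, dS_max: float) -> bool:
    """True iff the pair may interact: |S_j - S_k| < dS_max (strict).

    The boundary |S_j - S_k| == dS_max does not interact (the gating step
    function is taken to be 0 at 0).
    """
    if dS_max <= 0:
        raise ValueError(f"dS_max must be positive, got {dS_max!r}")
    return abs(S_j - S_k) < dS_max


def interaction_outcome(S_j: float, S_k: float, rng: np.random.Generator) -> int:
    """Deterministic contest outcome: returns 0 if j wins, 1 if k wins.

    The higher-ranked agent always wins; equal ranks are decided by a fair
    coin from ``rng``.
    """
    if S_j > S_k:
        return 0
    if S_k > S_j:
        return 1
    return 0 if rng.random() < 0.5 else 1


def apply_outcome(winner_S: float, loser_S: float,
                  delta_plus: float = 1.0,
                  delta_minus: float = 0.0) -> tuple[float, float]:
    """Rank updates after a contest: winner + delta_plus, loser - delta_minus.

    The loser's rank is floored at zero (ranks are non-negative by
    construction); with the default delta_minus = 0 it is unchanged.
    """
    return winner_S + delta_plus, max(loser_S - delta_minus, 0.0)


def resolve_site(agent_ids: Sequence[int], ranks: np.ndarray, params,
                 rng: np.random.Generator) -> list[InteractionResult]:
    """Resolve the interactions at one multiply-occupied lattice site.

    ``agent_ids`` are the agents sharing the site (ascending id order);
    ``ranks`` is the full rank array, updated in place.  In the default
    ``pair_mode == "single"`` exactly one unordered pair is drawn uniformly
    at random; with ``"all"`` every unordered pair is resolved once, in
    random order, with the gate re-evaluated against the running ranks.
    """
    c = len(agent_ids)
    if c < 2:
        return []

    def _attempt(j: int, k: int) -> InteractionResult:
        if not interaction_gate(ranks[j], ranks[k], params.dS_max):
            return InteractionResult(j, k, occurred=False)
        w = interaction_outcome(ranks[j], ranks[k], rng)
        winner, loser = (j, k) if w == 0 else (k, j)
        ranks[winner], ranks[loser] = apply_outcome(
            ranks[winner], ranks[loser], params.delta_plus, params.delta_minus
        )
        return InteractionResult(j, k, occurred=True, winner=winner, loser=loser)

    if getattr(params, "pair_mode", "single") == "all":
        pairs = [(agent_ids[a], agent_ids[b])
                 for a in range(c) for b in range(a + 1, c)]
        # Fisher-Yates, same draw sequence as the compiled loop
        for q in range(len(pairs) - 1, 0, -1):
            j2 = randint_below(rng, q + 1)
            pairs[q], pairs[j2] = pairs[j2], pairs[q]
        return [_attempt(j, k) for j, k in pairs]

    a = randint_below(rng, c)
    b = randint_below(rng, c - 1)
    if b >= a:
        b += 1
    return [_attempt(agent_ids[a], agent_ids[b])]
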