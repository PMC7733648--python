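"""Chance-pairing probability under random mate choice.

With n breeding pairs (including singletons) and a 50/50 sex ratio, a female
re-choosing a mate at random each season picks the same male again with
probability 1/(n−1) per extra season, so the probability of keeping one mate
across y seasons is

    p = (1 / (n − 1)) ** (y − 1).

Small p means the observed repeat pairing is unlikely under random mate
choice — evidence for an active multi-year pair-bond.  The critical pool size
is the largest n at which p still reaches a significance level alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "PairingScenario",
    "chance_pairing_probability",
    "critical_pool_size",
    "joint_repeat_probability",
]


@dataclass(frozen=True)
class PairingScenario:
    """One observed repeat pairing: n pairs in the pool, y years with the same mate."""

    n: int
    y: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2 (need at least one alternative mate)")
        if self.y < 1:
            raise ValueError("y must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def chance_pairing_probability(n: int, y: int) -> float:
    """P(same mate for y years | random choice among n pairs incl. singletons)."""
    if n < 2:
        raise ValueError("n must be >= 2 (no alternative mates otherwise)")
    if y < 1:
        raise ValueError("y must be >= 1")
    return (1.0 / (n - 1)) ** (y - 1)


def critical_pool_size(y: int, alpha: float) -> int:
    """Largest n >= 2 with chance_pairing_probability(n, y) >= alpha.

    For y >= 2 this is the pool size at which a repeat pairing stops being
    significant at level alpha; smaller pools cannot distinguish pair-bonding
    from chance.
    """
    if y < 2:
        raise ValueError("y must be >= 2 (y = 1 is always probability 1)")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    # p(n) = (n−1)^−(y−1) >= alpha  ⇔  n − 1 <= alpha^(−1/(y−1))
    n = 2 + int(math.floor(alpha ** (-1.0 / (y - 1)) + 1e-12)) - 1
    # guard against floating-point boundary error with an exact integer check
    while chance_pairing_probability(n + 1, y) >= alpha:
        n += 1
    while n > 2 and chance_pairing_probability(n, y) < alpha:
        n -= 1
    return max(n, 2)


def joint_repeat_probability(scenarios: Sequence[PairingScenario]) -> float:
    """Probability of all observed repeat pairings jointly, assuming the
    females choose independently (product of per-scenario probabilities)."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    p = 1.0
    for s in scenarios:
        p *= chance_pairing_probability(s.n, s.y)
    return p
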