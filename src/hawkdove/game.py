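"""Two-strategy hawk-dove contest game: payoffs, the analytic mixed
equilibrium, and expected-payoff utilities.

The game is the classic 2x2 contest over a resource of value ``b``:
two hawks escalate and split both the resource and a fight cost ``c``
(payoff ``(b - c) / 2`` each), a hawk takes everything from a dove
(``b`` vs ``0``), and two doves share peacefully (``b / 2`` each).
For ``c > b`` the stable mixture of pure strategists contains hawks at
frequency ``b / c``; for ``b >= c`` hawks take over entirely.

These closed forms are used throughout the test-suite as analytic
oracles for the agent-based simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Strategy",
    "GameParams",
    "payoff",
    "ess_hawk_frequency",
    "expected_payoffs",
]


class Strategy(Enum):
    """Pure strategy of an agent. Agents never play mixed strategies."""

    DOVE = 0
    HAWK = 1

    @property
    def code(self) -> int:
        """Integer code used by the array-backed population (HAWK=1)."""
        return self.value


@dataclass(frozen=True)
class GameParams:
    """Benefit/cost parameters of the contest game.

    Parameters
    ----------
    benefit
        Value ``b`` of the contested resource (must be positive).
    cost
        Cost ``c`` paid by each hawk in a hawk-hawk fight (must be
        positive). Payoffs are real-valued: sweeps use non-integer
        costs such as 6.67, so no integer arithmetic anywhere.
    """

    benefit: float = 6.0
    cost: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "benefit", float(self.benefit))
        object.__setattr__(self, "cost", float(self.cost))
        if not self.benefit > 0:
            raise ValueError(f"benefit must be > 0, got {self.benefit}")
        if not self.cost > 0:
            raise ValueError(f"cost must be > 0, got {self.cost}")


def payoff(
    own: Strategy, opponent: Strategy, params: GameParams
) -> tuple[float, float]:
    """Payoff pair ``(to self, to opponent)`` for one contest.

    Total on its domain; hawk-hawk payoffs are negative whenever
    ``cost > benefit``.
    """
    b, c = params.benefit, params.cost
    if own is Strategy.HAWK:
        if opponent is Strategy.HAWK:
            half = (b - c) / 2.0
            return (half, half)
        return (b, 0.0)
    if opponent is Strategy.HAWK:
        return (0.0, b)
    return (b / 2.0, b / 2.0)


def ess_hawk_frequency(params: GameParams) -> float:
    """Evolutionarily stable hawk frequency, ``min(1, b / c)``.

    When the benefit meets or exceeds the cost the population is all
    hawks, so the frequency clamps at 1 instead of erroring.
    """
    if params.cost <= 0:
        raise ValueError("cost must be positive to compute b/c")
    return min(1.0, params.benefit / params.cost)


def expected_payoffs(
    hawk_freq: float, params: GameParams
) -> tuple[float, float]:
    """Expected payoff to a hawk and to a dove against a random opponent.

    The opponent is hawk with probability ``hawk_freq``. Returns
    ``(E[payoff | hawk], E[payoff | dove])``; the two are equal exactly
    at the mixed equilibrium ``hawk_freq = b / c`` (for ``c > b``).
    """
    if not 0.0 <= hawk_freq <= 1.0:
        raise ValueError(f"hawk_freq must lie in [0, 1], got {hawk_freq}")
    b, c = params.benefit, params.cost
    p = hawk_freq
    e_hawk = p * (b - c) / 2.0 + (1.0 - p) * b
    e_dove = (1.0 - p) * b / 2.0
    return (e_hawk, e_dove)
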