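"""Estimating a memory-one vector from observed play.

Any strategy — whatever its true memory depth — induces an empirical
memory-one vector: for each prior-round state s in (CC, CD, DC, DD),
the fraction of visits to s that were followed by a cooperation.  The
first turn conditions nothing (there is no prior state), so a history of
n turns yields n-1 transitions.  States never visited carry no
information; by default they are imputed with the focal player's overall
cooperation rate across the whole history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .algebra import DEFAULT_PAYOFFS, STATE_ORDER, PayoffParams
from .projection import project

__all__ = [
    "PlayHistory",
    "TransitionCounts",
    "MeasuredVector",
    "count_transitions",
    "measure_p",
    "measure_from_counts",
    "sse_trajectory",
]

_MOVES = frozenset("CD")


@dataclass(frozen=True)
class PlayHistory:
    """Two aligned move sequences over the alphabet {C, D}."""

    moves_x: tuple[str, ...]
    moves_y: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.moves_x) != len(self.moves_y):
            raise ValueError(
                f"move sequences differ in length: "
                f"{len(self.moves_x)} vs {len(self.moves_y)}"
            )
        bad = (set(self.moves_x) | set(self.moves_y)) - _MOVES
        if bad:
            raise ValueError(f"moves must be 'C' or 'D'; found {sorted(bad)}")

    @classmethod
    def from_strings(cls, x: str, y: str) -> "PlayHistory":
        return cls(tuple(x), tuple(y))

    def __len__(self) -> int:
        return len(self.moves_x)

    def swapped(self) -> "PlayHistory":
        """The same match seen from the other player's side."""
        return PlayHistory(self.moves_y, self.moves_x)

    def prefix(self, n: int) -> "PlayHistory":
        return PlayHistory(self.moves_x[:n], self.moves_y[:n])


@dataclass(frozen=True)
class TransitionCounts:
    """Per-state visit and cooperation tallies for one player.

    ``visits[s]`` counts transitions observed out of state s and
    ``coops[s]`` how many of them were followed by a cooperation, for s
    in the order (CC, CD, DC, DD).  ``overall_coop_rate`` is the focal
    player's cooperation fraction over all turns (the default imputation
    value for unvisited states).
    """

    visits: tuple[int, int, int, int]
    coops: tuple[int, int, int, int]
    overall_coop_rate: float
    n_turns: int

    def __post_init__(self) -> None:
        for c, v in zip(self.coops, self.visits):
            if not 0 <= c <= v:
                raise ValueError(f"invalid tallies: coops {self.coops} vs visits {self.visits}")

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        """Pool tallies across repeated matches (counts summed, rate re-weighted)."""
        n = self.n_turns + other.n_turns
        rate = (
            self.overall_coop_rate * self.n_turns
            + other.overall_coop_rate * other.n_turns
        ) / n
        return TransitionCounts(
            visits=tuple(a + b for a, b in zip(self.visits, other.visits)),
            coops=tuple(a + b for a, b in zip(self.coops, other.coops)),
            overall_coop_rate=rate,
            n_turns=n,
        )


@dataclass(frozen=True)
class MeasuredVector:
    """An estimated memory-one vector with its imputation record."""

    p_hat: np.ndarray
    imputed_mask: tuple[bool, bool, bool, bool]
    counts: TransitionCounts


def _state_index(own: str, opp: str) -> int:
    return ("C", "D").index(own) * 2 + ("C", "D").index(opp)


def count_transitions(
    history: PlayHistory, perspective: Literal["focal", "coplayer"] = "focal"
) -> TransitionCounts:
    """Tally per-state visits and subsequent cooperations from a history.

    Under the ``coplayer`` perspective the roles are reversed, i.e. the
    result equals the focal count of the swapped history.
    """
    if perspective == "coplayer":
        history = history.swapped()
    elif perspective != "focal":
        raise ValueError(f"unknown perspective {perspective!r}")
    n = len(history)
    if n < 2:
        raise ValueError("need at least 2 turns to observe a transition")
    visits = [0, 0, 0, 0]
    coops = [0, 0, 0, 0]
    mx, my = history.moves_x, history.moves_y
    for t in range(n - 1):
        s = _state_index(mx[t], my[t])
        visits[s] += 1
        if mx[t + 1] == "C":
            coops[s] += 1
    rate = mx.count("C") / n
    return TransitionCounts(tuple(visits), tuple(coops), rate, n)


def measure_from_counts(
    counts: TransitionCounts,
    imputation: str | float = "overall_rate",
) -> MeasuredVector:
    """Form p_hat = coops/visits with the given policy for unvisited states.

    ``imputation`` is ``"overall_rate"`` (default: fill with the focal
    player's overall cooperation rate), a float in [0, 1] (fixed fill
    value), or ``"none"`` (raise if any state is unvisited).
    """
    p_hat = np.empty(4)
    mask = []
    missing = []
    for s, (c, v) in enumerate(zip(counts.coops, counts.visits)):
        if v > 0:
            p_hat[s] = c / v
            mask.append(False)
        else:
            missing.append(STATE_ORDER[s])
            mask.append(True)
            if imputation == "overall_rate":
                p_hat[s] = counts.overall_coop_rate
            elif isinstance(imputation, (int, float)) and not isinstance(imputation, bool):
                if not 0 <= imputation <= 1:
                    raise ValueError("fixed imputation value must lie in [0, 1]")
                p_hat[s] = float(imputation)
            elif imputation == "none":
                pass  # error raised below once all missing states are known
            else:
                raise ValueError(f"unknown imputation policy {imputation!r}")
    if missing and imputation == "none":
        raise ValueError(
            f"states never visited: {', '.join(missing)} (imputation disabled)"
        )
    return MeasuredVector(p_hat=p_hat, imputed_mask=tuple(mask), counts=counts)


def measure_p(
    history: PlayHistory,
    perspective: Literal["focal", "coplayer"] = "focal",
    imputation: str | float = "overall_rate",
) -> MeasuredVector:
    """Estimate the focal player's memory-one vector from one history."""
    return measure_from_counts(count_transitions(history, perspective), imputation)


def sse_trajectory(
    history: PlayHistory,
    payoffs: PayoffParams = DEFAULT_PAYOFFS,
    perspective: Literal["focal", "coplayer"] = "focal",
    imputation: str | float = "overall_rate",
) -> list[tuple[int, float]]:
    """SSE of the measured vector as a function of history length.

    For each prefix length t = 2..n, measures p_hat from the first t
    turns and records the SSE of its projection onto the extortion
    subspace.  Averaging across repeated histories is the caller's
    concern.  Counting is incremental, so the whole trajectory costs
    O(n) tally updates plus one 4x2 projection per prefix.
    """
    if perspective == "coplayer":
        history = history.swapped()
    n = len(history)
    if n < 2:
        raise ValueError("need at least 2 turns")
    visits = [0, 0, 0, 0]
    coops = [0, 0, 0, 0]
    mx, my = history.moves_x, history.moves_y
    n_coop = 1 if mx[0] == "C" else 0
    out: list[tuple[int, float]] = []
    for t in range(1, n):
        s = _state_index(mx[t - 1], my[t - 1])
        visits[s] += 1
        if mx[t] == "C":
            coops[s] += 1
            n_coop += 1
        counts = TransitionCounts(
            tuple(visits), tuple(coops), n_coop / (t + 1), t + 1
        )
        mv = measure_from_counts(counts, imputation)
        out.append((t + 1, project(mv.p_hat, payoffs).sse))
    return out
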