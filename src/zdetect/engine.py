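"""Seeded IPD match simulation and exact Markov stationary analysis.

A match between two memory-one strategies is a Markov chain on the four
joint states (CC, CD, DC, DD); its stationary distribution gives the
players' exact long-run per-turn scores, which serve as the analytic
oracle for the simulator.  The simulator itself supports memory-one
strategies (probabilistic, with an initial move) and deterministic cycle
strategies, optional per-move noise, and is bit-reproducible given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .algebra import DEFAULT_PAYOFFS, PayoffParams, as_memory_one, extortionate_vector
from .measurement import PlayHistory

__all__ = [
    "StrategySpec",
    "MatchResult",
    "play_match",
    "stationary_state",
    "stationary_scores",
    "default_corpus",
    "get_strategy",
]

#: Co-player state permutation: state (a, b) seen from the other side is (b, a).
_SWAP = np.array([0, 2, 1, 3])


@dataclass(frozen=True)
class StrategySpec:
    """A named strategy the engine can play.

    ``kind`` is ``"memory_one"`` (vector of four cooperation
    probabilities plus an initial move) or ``"cycle"`` (a deterministic
    move sequence repeated forever, e.g. "CCD"; a stand-in for simple
    longer-memory behaviour that the measurement module can still
    profile).
    """

    name: str
    kind: str = "memory_one"
    vector: tuple[float, float, float, float] | None = None
    initial: str = "C"
    cycle: str | None = None
    zd_params: tuple[float, float, float] | None = None  # (alpha, beta, gamma) if ZD

    def __post_init__(self) -> None:
        if self.kind == "memory_one":
            if self.vector is None:
                raise ValueError(f"memory-one strategy {self.name!r} needs a vector")
            as_memory_one(self.vector)
            if self.initial not in ("C", "D"):
                raise ValueError("initial move must be 'C' or 'D'")
        elif self.kind == "cycle":
            if not self.cycle or set(self.cycle) - set("CD"):
                raise ValueError(f"cycle strategy {self.name!r} needs a C/D sequence")
        else:
            raise ValueError(f"unknown strategy kind {self.kind!r}")

    @property
    def p(self) -> np.ndarray:
        if self.vector is None:
            raise ValueError(f"{self.name!r} has no memory-one vector")
        return np.asarray(self.vector, dtype=float)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one simulated match."""

    history: PlayHistory
    score_x: float
    score_y: float
    per_turn_x: float
    per_turn_y: float
    state_freq: np.ndarray  # empirical distribution over (CC, CD, DC, DD)
    winner: str  # "x", "y" or "tie"

    @property
    def p_dd(self) -> float:
        """Empirical probability of mutual defection."""
        return float(self.state_freq[3])


def _next_move_memory_one(p: np.ndarray, state: int, u: float) -> str:
    return "C" if u < p[state] else "D"


def play_match(
    x: StrategySpec,
    y: StrategySpec,
    turns: int,
    seed: int,
    noise: float = 0.0,
    payoffs: PayoffParams = DEFAULT_PAYOFFS,
) -> MatchResult:
    """Play one seeded match of ``turns`` rounds between x and y.

    Each round, a memory-one player cooperates with its state-conditional
    probability (initial move on round 1); a cycle player emits its next
    scheduled move.  With ``noise`` > 0 every emitted move is flipped
    independently with that probability.  Identical seeds give identical
    histories.
    """
    if turns < 1:
        raise ValueError("turns must be >= 1")
    if not 0 <= noise < 1:
        raise ValueError("noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    u_x = rng.random(turns)
    u_y = rng.random(turns)
    flips = rng.random((turns, 2)) < noise if noise > 0 else None

    moves_x: list[str] = []
    moves_y: list[str] = []
    state = -1
    for t in range(turns):
        if x.kind == "cycle":
            mx = x.cycle[t % len(x.cycle)]
        elif t == 0:
            mx = x.initial
        else:
            mx = _next_move_memory_one(x.p, state, u_x[t])
        if y.kind == "cycle":
            my = y.cycle[t % len(y.cycle)]
        elif t == 0:
            my = y.initial
        else:
            my = _next_move_memory_one(y.p, _SWAP[state], u_y[t])
        if flips is not None:
            if flips[t, 0]:
                mx = "D" if mx == "C" else "C"
            if flips[t, 1]:
                my = "D" if my == "C" else "C"
        moves_x.append(mx)
        moves_y.append(my)
        state = ("C", "D").index(mx) * 2 + ("C", "D").index(my)

    history = PlayHistory(tuple(moves_x), tuple(moves_y))
    S_x, S_y = payoffs.S_x, payoffs.S_y
    states = np.array(
        [("C", "D").index(a) * 2 + ("C", "D").index(b)
         for a, b in zip(moves_x, moves_y)]
    )
    counts = np.bincount(states, minlength=4)
    score_x = float(S_x[states].sum())
    score_y = float(S_y[states].sum())
    if score_x > score_y:
        winner = "x"
    elif score_y > score_x:
        winner = "y"
    else:
        winner = "tie"
    return MatchResult(
        history=history,
        score_x=score_x,
        score_y=score_y,
        per_turn_x=score_x / turns,
        per_turn_y=score_y / turns,
        state_freq=counts / turns,
        winner=winner,
    )


def transition_matrix(p, q) -> np.ndarray:
    """The 4x4 Markov matrix of a memory-one pair over (CC, CD, DC, DD).

    From state s the focal player cooperates with probability p[s] and
    the co-player with probability q[swap(s)].
    """
    p = as_memory_one(p)
    q = as_memory_one(q)
    M = np.empty((4, 4))
    for s in range(4):
        px = p[s]
        py = q[_SWAP[s]]
        M[s] = [px * py, px * (1 - py), (1 - px) * py, (1 - px) * (1 - py)]
    return M


def stationary_state(p, q, fallback_epsilon: float | None = None) -> np.ndarray:
    """Unique stationary distribution of the match chain of (p, q).

    Solves v M = v, sum(v) = 1.  When the chain is not ergodic (several
    stationary distributions, typical for deterministic strategies such
    as TFT vs TFT) the solution is not unique; by default that raises
    ``ValueError``.  Passing ``fallback_epsilon`` perturbs every
    cooperation probability into the open interval by that amount and
    solves the perturbed chain instead.
    """
    M = transition_matrix(p, q)
    ns = scipy.linalg.null_space(M.T - np.eye(4))
    if ns.shape[1] != 1:
        if fallback_epsilon is None:
            raise ValueError(
                "match chain is not ergodic: stationary distribution not unique "
                "(pass fallback_epsilon to perturb, or use simulation)"
            )
        eps = fallback_epsilon
        p = np.clip(as_memory_one(p), eps, 1 - eps)
        q = np.clip(as_memory_one(q), eps, 1 - eps)
        M = transition_matrix(p, q)
        ns = scipy.linalg.null_space(M.T - np.eye(4))
        if ns.shape[1] != 1:
            raise ValueError("perturbed chain still degenerate")
    v = ns[:, 0]
    v = v / v.sum()
    if np.any(v < -1e-9):
        raise ValueError("numerical failure: negative stationary mass")
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


def stationary_scores(
    p, q, payoffs: PayoffParams = DEFAULT_PAYOFFS,
    fallback_epsilon: float | None = None,
) -> tuple[float, float]:
    """Exact long-run per-turn scores (S_X, S_Y) of a memory-one pair."""
    v = stationary_state(p, q, fallback_epsilon)
    return float(v @ payoffs.S_x), float(v @ payoffs.S_y)


def _zd_params(chi: float, phi: float, P: float) -> tuple[float, float, float]:
    return (phi, -phi * chi, -P * (phi - phi * chi))


def default_corpus(payoffs: PayoffParams = DEFAULT_PAYOFFS) -> dict[str, StrategySpec]:
    """The bundled named-strategy corpus (theoretic memory-one vectors).

    Covers the classic strategies plus a small zero-determinant family:
    extortionate members built from the (chi, phi) parametrisation and
    the generous ZD-GTFT-2.  Initial move is C except for Defector.
    """
    P = payoffs.P
    specs = [
        StrategySpec("Cooperator", vector=(1, 1, 1, 1)),
        StrategySpec("Defector", vector=(0, 0, 0, 0), initial="D"),
        StrategySpec("Alternator", vector=(0, 0, 1, 1)),
        StrategySpec("TitForTat", vector=(1, 0, 1, 0)),
        StrategySpec("WSLS", vector=(1, 0, 0, 1)),
        StrategySpec("GTFT", vector=(1, 1 / 3, 1, 1 / 3)),
        StrategySpec("Joss", vector=(0.9, 0, 0.9, 0)),
        StrategySpec(
            "Extort-2",
            vector=(8 / 9, 1 / 2, 1 / 3, 0),
            zd_params=_zd_params(2.0, 1 / 18, P),
        ),
        StrategySpec(
            "ZD-Extort-3",
            vector=tuple(extortionate_vector(3.0, 1 / 26, payoffs)),
            zd_params=_zd_params(3.0, 1 / 26, P),
        ),
        StrategySpec(
            "ZD-Extort-4",
            vector=tuple(extortionate_vector(4.0, 1 / 34, payoffs)),
            zd_params=_zd_params(4.0, 1 / 34, P),
        ),
        StrategySpec("ZD-GTFT-2", vector=(1, 1 / 8, 1, 1 / 4)),
    ]
    return {s.name: s for s in specs}


def get_strategy(name: str, payoffs: PayoffParams = DEFAULT_PAYOFFS) -> StrategySpec:
    """Look up a bundled strategy by (case-insensitive) name."""
    corpus = default_corpus(payoffs)
    lookup = {k.lower(): v for k, v in corpus.items()}
    key = name.lower()
    if key not in lookup:
        raise KeyError(
            f"unknown strategy {name!r}; bundled: {', '.join(sorted(corpus))}"
        )
    return lookup[key]
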