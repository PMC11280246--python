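"""Evolutionary dynamics over a measured payoff matrix.

Two standard models of selection are provided.  The continuous replicator
equation on the simplex,

    dgamma_i/dt = gamma_i * ((S gamma)_i - gamma^T S gamma),

grows the share of strategies whose payoff against the current population
exceeds the population mean; its stationary points describe which
strategies survive long-run selection.  The discrete Moran process models
a finite population of N individuals under fitness-proportional
birth-death updating; the quantity of interest is the fixation
probability kappa_1 of a single invader, conventionally compared to the
neutral value 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .algebra import DEFAULT_PAYOFFS, PayoffParams
from .engine import StrategySpec, play_match

__all__ = [
    "ReplicatorResult",
    "FixationEstimate",
    "replicator_solve",
    "moran_fixation_exact",
    "moran_fixation_sim",
]


@dataclass(frozen=True)
class ReplicatorResult:
    """Final population state of a replicator integration."""

    gamma: np.ndarray
    converged: bool
    t_final: float


@dataclass(frozen=True)
class FixationEstimate:
    """Fixation probability of a single invader in a population of size N."""

    kappa1: float
    N: int
    reps: int | None = None  # None for the exact birth-death formula

    @property
    def normalised(self) -> float:
        """kappa_1 * N — above 1 means better-than-neutral invasion."""
        return self.kappa1 * self.N

    @property
    def standard_error(self) -> float | None:
        if self.reps is None:
            return None
        return float(np.sqrt(self.kappa1 * (1 - self.kappa1) / self.reps))


def replicator_solve(
    S: np.ndarray,
    gamma0: np.ndarray | None = None,
    tol: float = 1e-10,
    t_max: float = 1e5,
) -> ReplicatorResult:
    """Integrate the replicator equation until the flow is stationary.

    Stops when the infinity norm of dgamma/dt drops below ``tol`` or the
    time horizon ``t_max`` is exhausted (``converged`` is then False but
    the final state is still returned).  The state is renormalised onto
    the simplex after each integration chunk to counter drift.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("payoff matrix must be square")
    if np.any(~np.isfinite(S)):
        raise ValueError("payoff matrix contains non-finite entries")
    if gamma0 is None:
        gamma = np.full(n, 1.0 / n)
    else:
        gamma = np.asarray(gamma0, dtype=float)
        if gamma.shape != (n,) or np.any(gamma < 0) or abs(gamma.sum() - 1) > 1e-9:
            raise ValueError("gamma0 must be a probability vector of matching length")

    def flow(_t, g):
        fitness = S @ g
        mean = g @ fitness
        return g * (fitness - mean)

    t = 0.0
    chunk = 10.0
    while t < t_max:
        sol = solve_ivp(
            flow, (t, min(t + chunk, t_max)), gamma,
            method="RK45", rtol=1e-10, atol=1e-14,
        )
        gamma = np.clip(sol.y[:, -1], 0.0, None)
        gamma /= gamma.sum()
        t = sol.t[-1]
        if np.max(np.abs(flow(t, gamma))) < tol:
            return ReplicatorResult(gamma=gamma, converged=True, t_final=t)
        chunk = min(chunk * 2, 1e4)
    return ReplicatorResult(gamma=gamma, converged=False, t_final=t)


def moran_fixation_exact(a: float, b: float, c: float, d: float, N: int) -> FixationEstimate:
    """Exact fixation probability of one invader under the Moran process.

    The 2x2 game has per-interaction payoffs a (invader vs invader),
    b (invader vs resident), c (resident vs invader) and d (resident vs
    resident).  With j invaders present, average payoffs excluding
    self-interaction are

        f_j = (a(j-1) + b(N-j)) / (N-1),   g_j = (cj + d(N-j-1)) / (N-1),

    and fitness-proportional birth with uniform death gives

        kappa_1 = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} g_j / f_j).

    For a neutral game (a=b=c=d) this reduces to 1/N.
    """
    if N < 2:
        raise ValueError("population size must be >= 2")
    ratios = []
    for j in range(1, N):
        f = (a * (j - 1) + b * (N - j)) / (N - 1)
        g = (c * j + d * (N - j - 1)) / (N - 1)
        if f < 0 or g < 0:
            raise ValueError("fitness must be nonnegative for proportional selection")
        if f == 0 and g == 0:
            raise ValueError(f"degenerate game: zero total fitness at {j} invaders")
        if f == 0:
            # the invader lineage can never grow past j, so it never fixes
            return FixationEstimate(kappa1=0.0, N=N)
        ratios.append(g / f)
    kappa1 = 1.0 / (1.0 + np.cumprod(ratios).sum())
    return FixationEstimate(kappa1=float(kappa1), N=N)


def moran_fixation_sim(
    x: StrategySpec,
    y: StrategySpec,
    N: int,
    turns: int,
    reps: int,
    seed: int,
    payoffs: PayoffParams = DEFAULT_PAYOFFS,
) -> FixationEstimate:
    """Monte-Carlo fixation probability of one x-invader among y-residents.

    Each generation the three distinct pairings (x-x, x-y, y-y) are
    scored by fresh seeded matches of ``turns`` rounds; an individual's
    fitness is its mean per-turn score against the rest of the population
    (self-interaction excluded).  One individual is chosen to reproduce
    with probability proportional to fitness and replaces a uniformly
    chosen individual.  The estimate is the fraction of ``reps``
    independent runs in which the invader lineage fixes.
    """
    if N < 2:
        raise ValueError("population size must be >= 2")
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(reps)]
    fixed = 0
    for rng in rngs:
        j = 1  # number of invaders
        while 0 < j < N:
            s_xx = (
                play_match(x, x, turns, int(rng.integers(2**31)), 0.0, payoffs).per_turn_x
                if j > 1 else 0.0
            )
            s_yy = (
                play_match(y, y, turns, int(rng.integers(2**31)), 0.0, payoffs).per_turn_x
                if j < N - 1 else 0.0
            )
            m_xy = play_match(x, y, turns, int(rng.integers(2**31)), 0.0, payoffs)
            s_xy, s_yx = m_xy.per_turn_x, m_xy.per_turn_y
            f_x = (s_xx * (j - 1) + s_xy * (N - j)) / (N - 1)
            f_y = (s_yx * j + s_yy * (N - j - 1)) / (N - 1)
            if f_x < 0 or f_y < 0:
                raise ValueError("fitness must be nonnegative for proportional selection")
            total = j * f_x + (N - j) * f_y
            if total == 0:
                raise ValueError("degenerate generation: zero total fitness")
            birth_is_x = rng.random() < j * f_x / total
            death_is_x = rng.random() < j / N
            if birth_is_x and not death_is_x:
                j += 1
            elif death_is_x and not birth_is_x:
                j -= 1
        if j == N:
            fixed += 1
    return FixationEstimate(kappa1=fixed / reps, N=N, reps=reps)
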