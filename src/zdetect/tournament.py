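"""Round-robin tournaments and per-strategy extortion summaries.

Every pair of strategies plays a repeated match; transition counts are
pooled across repetitions before forming the measured memory-one vector
(summing counts is the maximum-likelihood pooling — it stabilises rarely
visited states), which is then projected to give the pairing's SSE and
measured chi.  Per-strategy summaries aggregate over opponents: score
per turn, win rate, probability of mutual defection, median chi and the
moments (mean / median / variance / skew) of the SSE distribution.  A
negatively skewed SSE — usually far from the extortion plane but with a
left tail of extortionate episodes — is the signature of an adaptable
strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .algebra import DEFAULT_PAYOFFS, PayoffParams
from .engine import StrategySpec, play_match
from .measurement import TransitionCounts, count_transitions, measure_from_counts
from .projection import project

__all__ = [
    "PairRecord",
    "round_robin",
    "summarize",
    "skewness",
    "records_frame",
    "payoff_matrix",
    "measured_chi",
]


@dataclass(frozen=True)
class PairRecord:
    """One strategy's view of one pairing, pooled over repetitions."""

    strategy: str
    opponent: str
    counts: TransitionCounts
    p_hat: np.ndarray
    imputed_mask: tuple[bool, bool, bool, bool]
    sse: float
    chi_hat: float | None
    p_dd: float
    mean_score_per_turn: float
    opponent_score_per_turn: float
    wins: int
    losses: int
    ties: int


def round_robin(
    corpus: dict[str, StrategySpec] | list[StrategySpec],
    turns: int,
    reps: int,
    seed: int,
    payoffs: PayoffParams = DEFAULT_PAYOFFS,
    noise: float = 0.0,
    include_self: bool = False,
    imputation: str | float = "overall_rate",
) -> list[PairRecord]:
    """Play every pairing ``reps`` times and record both perspectives.

    Each repetition uses a distinct seed derived from ``seed`` via a
    seed sequence, so the whole tournament is reproducible.  Transition
    counts are pooled across repetitions per pairing before measurement;
    SSE and chi come from projecting the pooled estimate.
    """
    if isinstance(corpus, dict):
        specs = list(corpus.values())
    else:
        specs = list(corpus)
    if len(specs) < 2:
        raise ValueError("need at least two strategies")
    pairs = list(combinations(range(len(specs)), 2))
    if include_self:
        pairs += [(i, i) for i in range(len(specs))]

    root = np.random.SeedSequence(seed)
    match_seeds = root.generate_state(len(pairs) * reps).astype(np.int64)

    records: list[PairRecord] = []
    k = 0
    for i, j in pairs:
        x, y = specs[i], specs[j]
        counts_x: TransitionCounts | None = None
        counts_y: TransitionCounts | None = None
        wins_x = wins_y = ties = 0
        score_x = score_y = 0.0
        p_dd = 0.0
        for _ in range(reps):
            result = play_match(x, y, turns, int(match_seeds[k]), noise, payoffs)
            k += 1
            cx = count_transitions(result.history, "focal")
            cy = count_transitions(result.history, "coplayer")
            counts_x = cx if counts_x is None else counts_x + cx
            counts_y = cy if counts_y is None else counts_y + cy
            score_x += result.per_turn_x
            score_y += result.per_turn_y
            p_dd += result.p_dd
            if result.winner == "x":
                wins_x += 1
            elif result.winner == "y":
                wins_y += 1
            else:
                ties += 1
        for spec, opp, counts, s_own, s_opp, w, l in (
            (x, y, counts_x, score_x, score_y, wins_x, wins_y),
            (y, x, counts_y, score_y, score_x, wins_y, wins_x),
        ):
            mv = measure_from_counts(counts, imputation)
            res = project(mv.p_hat, payoffs)
            records.append(
                PairRecord(
                    strategy=spec.name,
                    opponent=opp.name,
                    counts=counts,
                    p_hat=mv.p_hat,
                    imputed_mask=mv.imputed_mask,
                    sse=res.sse,
                    chi_hat=res.chi_hat,
                    p_dd=p_dd / reps,
                    mean_score_per_turn=s_own / reps,
                    opponent_score_per_turn=s_opp / reps,
                    wins=w,
                    losses=l,
                    ties=ties,
                )
            )
    return records


def skewness(sample) -> float:
    """Adjusted Fisher–Pearson sample skewness g1 * sqrt(n(n-1)) / (n-2).

    Returns 0 for a zero-variance sample and NaN for n < 3 (undefined).
    """
    a = np.asarray(sample, dtype=float)
    n = a.size
    if n < 3:
        return float("nan")
    scale = max(1.0, float(np.mean(np.abs(a))) ** 2)
    if np.var(a) <= 1e-24 * scale:  # numerically constant sample
        return 0.0
    return float(scipy.stats.skew(a, bias=False))


def summarize(records: list[PairRecord]) -> pd.DataFrame:
    """Per-strategy aggregation over opponents.

    Returns a DataFrame indexed by strategy with columns: score_per_turn,
    p_win, p_dd, median_chi (over defined chi only, with n_chi_undefined
    reported), sse_mean, sse_median, sse_var, sse_skew and n_opponents.
    Opponents are weighted equally.
    """
    rows = {}
    by_strategy: dict[str, list[PairRecord]] = {}
    for r in records:
        by_strategy.setdefault(r.strategy, []).append(r)
    for name, recs in by_strategy.items():
        sses = np.array([r.sse for r in recs])
        chis = [r.chi_hat for r in recs if r.chi_hat is not None]
        matches = [r.wins + r.losses + r.ties for r in recs]
        rows[name] = {
            "score_per_turn": np.mean([r.mean_score_per_turn for r in recs]),
            "p_win": sum(r.wins for r in recs) / sum(matches),
            "p_dd": np.mean([r.p_dd for r in recs]),
            "median_chi": float(np.median(chis)) if chis else float("nan"),
            "n_chi_undefined": len(recs) - len(chis),
            "sse_mean": float(sses.mean()),
            "sse_median": float(np.median(sses)),
            "sse_var": float(sses.var(ddof=1)) if len(sses) > 1 else 0.0,
            "sse_skew": skewness(sses),
            "n_opponents": len(recs),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "strategy"
    return df


def measured_chi(
    records: list[PairRecord],
    strategy: str,
    payoffs: PayoffParams = DEFAULT_PAYOFFS,
    imputation: str | float = "overall_rate",
):
    """Tournament-level measured vector for one strategy.

    Pools the strategy's transition counts across *all* opponents and
    repetitions before measuring and projecting — the estimator behind a
    single per-strategy "measured chi" figure.  States that some pairings
    never visit are still measured as long as any opponent elicits them.
    Returns the :class:`~zdetect.projection.ProjectionResult`.
    """
    total: TransitionCounts | None = None
    for r in records:
        if r.strategy == strategy:
            total = r.counts if total is None else total + r.counts
    if total is None:
        raise KeyError(f"no records for strategy {strategy!r}")
    mv = measure_from_counts(total, imputation)
    return project(mv.p_hat, payoffs)


def records_frame(records: list[PairRecord]) -> pd.DataFrame:
    """Flatten PairRecords into a DataFrame (one row per perspective)."""
    rows = []
    for r in records:
        rows.append(
            {
                "strategy": r.strategy,
                "opponent": r.opponent,
                "p1_hat": r.p_hat[0],
                "p2_hat": r.p_hat[1],
                "p3_hat": r.p_hat[2],
                "p4_hat": r.p_hat[3],
                "n_imputed": sum(r.imputed_mask),
                "sse": r.sse,
                "chi_hat": r.chi_hat if r.chi_hat is not None else float("nan"),
                "p_dd": r.p_dd,
                "score_per_turn": r.mean_score_per_turn,
                "opponent_score_per_turn": r.opponent_score_per_turn,
                "wins": r.wins,
                "losses": r.losses,
                "ties": r.ties,
            }
        )
    return pd.DataFrame(rows)


def payoff_matrix(records: list[PairRecord], names: list[str],
                  self_scores: dict[str, float] | None = None) -> np.ndarray:
    """Assemble the measured payoff matrix S (S_ij = score of i against j).

    Diagonal entries come from ``self_scores`` when given (e.g. from
    self-play matches or the analytic stationary score); otherwise the
    diagonal of a pairing of a strategy with itself defaults to NaN and
    must be filled by the caller.
    """
    idx = {n: i for i, n in enumerate(names)}
    S = np.full((len(names), len(names)), np.nan)
    for r in records:
        if r.strategy in idx and r.opponent in idx:
            S[idx[r.strategy], idx[r.opponent]] = r.mean_score_per_turn
    if self_scores:
        for n, s in self_scores.items():
            S[idx[n], idx[n]] = s
    return S
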