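# Methods

This note documents the models implemented in `zdetect`, the conventions
and numerical choices behind them, and what the bundled test conditions do
and do not demonstrate.

## Game and state conventions

The stage game is the Prisoner's Dilemma with payoffs `(R, S, T, P)`,
defaulting to `(3, 0, 5, 1)`, constrained by `T > R > P > S` and
`2R > T + S`; the default also satisfies `S + T − 2P ≠ 0`, which the
extortion-plane algebra requires (degenerate payoff sets are rejected with
an explicit error). Joint states of the previous round are always ordered
`(CC, CD, DC, DD)` with the **focal player's move first**; the focal payoff
vector is `S_x = (R, S, T, P)` and the co-player's is `S_y = (R, T, S, P)`.
Every module shares this convention. The tilde transforms are
`p̃ = (p1−1, p2−1, p3, p4)` for the focal player and `q̃ = (q1−1, q3, q2−1, q4)`
for the co-player (components 2 and 3 swap because the co-player sees each
joint state with roles reversed).

## Extortion algebra

A memory-one strategy is extortionate iff

- `p1 = [(R−P)(p2+p3) − R + T + S − P] / (S + T − 2P)` (the plane condition),
- `p4 = 0`, and
- `p2 + p3 < 1`,

with extortion factor
`χ = [p̃2(P−T) + p̃3(S−P)] / [p̃2(P−S) + p̃3(T−P)]`. The membership test
(`is_extortionate`) uses tolerance `1e−9`: the conditions are algebraic,
so the tolerance only absorbs floating-point error, and a diagnostic lists
which condition failed. Note that when `p̃2 = p̃3` the χ formula reduces to
`t(S−T)/t(T−S) = −1` for any payoffs: symmetric behaviour in the two
disagreement states can never look extortionate, which is why χ = −1
appears as the measured factor for strategies like unconditional defectors.

Construction (`make_zd`) inverts `p̃ = αS_x + βS_y + γ·1` and treats any
resulting component outside `[0, 1]` as an error rather than clipping —
silent clipping would produce a vector that no longer enforces the claimed
linear relation. The convenience `extortionate_vector(chi, phi)` uses the
one-parameter family `α = φ, β = −φχ, γ = −P(α+β)`; feasibility at the
default payoffs requires `φ ≤ 1/(4χ+1)`, and the bundled χ = 3 and χ = 4
extortioners use the midpoint `φ = 1/(2(4χ+1))` of that range, which puts
`p2 = 1/2` like the classic χ = 2 vector `(8/9, 1/2, 1/3, 0)`.

## Projection detector

`project` solves the normal equations `x* = (CᵀC)⁻¹Cᵀp̃` in closed form
(a 2×2 solve; `C` is checked to have rank 2). The SSE is computed both as
`‖Cx* − p̃‖²` and as `p̃ᵀp̃ − p̃ᵀCx*` and the two are asserted equal to
`1e−10` — a cheap internal consistency check on the linear algebra. χ is
reported as undefined when `|α̂| ≤ 1e−10` (`ALPHA_TOL`), since the ratio
`−β̂/α̂` is then numerically meaningless; classification treats such fits
as not-ZD regardless of SSE. The default classification threshold
`SSE ≤ 0.05` is a convenience only: it is exposed as a parameter and every
report carries the raw SSE and χ.

## Measurement from play

A history of `n` turns yields `n − 1` transitions; the first turn has no
prior state and conditions nothing (initial-move behaviour is not part of
a memory-one vector). For each state, `p̂_s = coops(s)/visits(s)`. States
never visited are imputed, by default with the focal player's overall
cooperation rate across all `n` turns of that matchup (per-matchup, not
pooled across opponents); a fixed value or a strict error mode are also
available, and the imputation mask is always reported. When repetitions of
the same pairing are pooled, counts are summed before forming ratios
(the maximum-likelihood estimate), never averaged as ratios.

`sse_trajectory` measures the projection SSE on every history prefix with
incremental counting (O(n) tallies plus one projection per prefix).
Averaging trajectories across repetitions or opponents is left to the
caller, since different study designs want different weightings.

## Match engine

Memory-one matches are simulated turn-by-turn with one uniform draw per
player per turn from a `numpy` PCG64 generator seeded explicitly; optional
noise flips each emitted move independently. Deterministic cycle
strategies (`kind="cycle"`) stand in for simple longer-memory behaviour.
The analytic oracle is the 4-state Markov chain whose transition from
state `s` multiplies the focal cooperation probability `p[s]` with the
co-player's `q[swap(s)]`; the stationary distribution is the 1-dimensional
null space of `Mᵀ − I`. Non-ergodic chains (deterministic strategies such
as TFT vs TFT) have no unique stationary distribution: the default is an
explicit error, with an opt-in ε-perturbation fallback (recommended
ε = 1e−6) for callers who want the limiting behaviour; simulation is the
primary route for deterministic pairs.

## Tournaments

`round_robin` plays every unordered pair of a corpus `reps` times with
seeds derived from one `SeedSequence`, records both perspectives, and
pools transition counts across repetitions before projecting. Self-play
pairings are excluded from the pair list by default (a pairing count of
`C(k,2) × 2` perspectives) but can be included with `include_self=True`,
which also supplies the diagonal of the measured payoff matrix; score
aggregation in the headline orderings includes self-interaction, since a
defector scoring `P` against itself while reciprocators score `R` is part
of why reciprocity outscores defection. Tournament-level measured χ
(`measured_chi`) pools one strategy's counts across **all** opponents and
repetitions before a single projection — states that some pairings never
visit (or visit only before absorption into mutual defection) are then
dominated by the pairings that do visit them, which is what makes the
recovered χ sharp. Wins are counted per repetition by total score, ties
counting for neither player; the median χ is taken over defined-χ records
only, with the undefined count reported; sample skewness is the adjusted
Fisher–Pearson statistic `g1·√(n(n−1))/(n−2)`, defined for `n ≥ 3` and
set to 0 for numerically constant samples.

## Evolutionary dynamics

The replicator equation `dγ_i/dt = γ_i((Sγ)_i − γᵀSγ)` is integrated with
adaptive RK45 (`rtol 1e−10`, `atol 1e−14`) in growing time chunks, with
renormalisation onto the simplex after each chunk; integration stops when
`‖dγ/dt‖∞ < tol` (default `1e−10`) or at `t_max` (default `1e5`), in which
case the state is returned with `converged=False` (cyclic games such as
rock–paper–scissors legitimately never converge). The mean-fitness term
is `γᵀSγ`, the only form that preserves the simplex.

The Moran process uses fitness-proportional birth and uniform death, with
fitness = average per-turn game score against the current population
excluding self-interaction (no exponential selection-intensity mapping;
the scheme is the simplest one whose neutral baseline is exactly `1/N`).
The exact fixation probability is the standard birth–death formula
`κ₁ = 1/(1 + Σ_k Π_j g_j/f_j)`; a zero invader fitness at some
intermediate count makes fixation impossible and returns `κ₁ = 0`. The
simulator scores each generation by fresh seeded matches between the three
distinct type pairings (invader–invader, invader–resident,
resident–resident) rather than per-individual matches — with only two
types present these are the only distinct matchups, and per-generation
resampling keeps the demographic and measurement noise.

## Synthetic study conditions

The bundled corpus holds theoretic memory-one vectors for Cooperator,
Defector, Alternator, Tit-For-Tat, Win-Stay-Lose-Shift, Generous
Tit-For-Tat `(1, 1/3, 1, 1/3)`, Joss `(0.9, 0, 0.9, 0)`, the χ = 2
extortioner `(8/9, 1/2, 1/3, 0)`, constructed χ = 3 and χ = 4
extortioners, and the generous ZD strategy `(1, 1/8, 1, 1/4)`; initial
move C except Defector. Validation matches run 2000 turns with 60
repetitions per pairing — the regime where pooled transition counts make
the measured χ of the χ = 2 extortioner stable to within a few hundredths.
The evolutionary analyses use a payoff matrix measured at 500 turns and
5 repetitions with self-play included, which is ample for the
per-turn-score differences (order 0.1–1) that drive the dynamics; the
headline tournament orderings use 1000 turns and 5 repetitions.

What these conditions emulate is noiseless, fixed-length repeated play
among a small, mostly memory-one corpus. They do not emulate: observation
noise or noisy environments (the engine supports noise, but no result here
depends on it), probabilistically ending matches, large heterogeneous
strategy corpora with learned/long-memory strategies, or mutation in the
evolutionary dynamics. Passing tests therefore show that the detector
recovers extortion factors from clean play histories and that extortion is
evolutionarily self-defeating *within this corpus*; they do not show
robustness of measurement under noise, nor evolutionary conclusions about
richer strategy spaces.

## Known limitations

- The projection is onto the extortion subspace only (`γ = −P(α+β)`);
  general ZD families with free `γ` (e.g. equalizers) are not classified,
  though generous ZD behaviour (`0 < χ ≤ 1` near the subspace) is labelled.
- A measured `p̂` near the subspace with `χ > 1` is evidence of
  extortionate *behaviour*, not proof the underlying strategy is ZD; only
  the converse direction (high SSE ⇒ not extortionate) is sound.
- Imputation biases the measured vector toward the overall cooperation
  rate for opponents that never elicit some states (e.g. unconditional
  cooperators leave `p2, p4` unmeasured); the imputation mask should be
  consulted before interpreting χ from such matchups.
- The Moran simulator's generation cost grows with absorption time;
  population sizes beyond a few dozen are better served by the exact
  formula on measured 2×2 scores.
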