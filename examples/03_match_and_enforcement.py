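"""Play seeded matches and verify the enforced linear score relation.

An extortionate strategy with factor chi forces (S_X - P) = chi (S_Y - P)
on the stationary scores against ANY opponent.  The exact Markov-chain
scores demonstrate this; a long simulated match agrees with them.
"""

from zdetect import get_strategy, play_match, stationary_scores

extort = get_strategy("Extort-2")  # chi = 2
opponent = (0.6, 0.4, 0.5, 0.3)  # an arbitrary fully-mixed memory-one opponent

sx, sy = stationary_scores(extort.p, opponent)
print(f"stationary scores: S_X = {sx:.4f}, S_Y = {sy:.4f}")
print(f"surplus ratio (S_X - P)/(S_Y - P) = {(sx - 1) / (sy - 1):.6f}  (chi = 2)")

from zdetect.engine import StrategySpec

match = play_match(extort, StrategySpec("opp", vector=opponent), turns=100_000, seed=7)
print(f"simulated per-turn scores over 1e5 turns: "
      f"{match.per_turn_x:.4f}, {match.per_turn_y:.4f}")
print(f"P(mutual defection) = {match.p_dd:.4f}")

# Both players would earn more if the extortioner cooperated fully, but
# whatever the opponent does, the extortioner's surplus is locked at
# twice the opponent's.
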