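"""Evolutionary fate of extortioners: replicator dynamics and Moran fixation.

A payoff matrix measured from tournament play feeds the replicator
equation; extortionate strategies are driven extinct while reciprocal
cooperators persist.  The Moran process quantifies invasion in finite
populations: a defector invades unconditional cooperators at a
better-than-neutral rate, but the neutral baseline kappa_1 = 1/N is
recovered exactly for identical strategies.
"""

import numpy as np

from zdetect import (
    default_corpus,
    get_strategy,
    moran_fixation_exact,
    moran_fixation_sim,
    payoff_matrix,
    replicator_solve,
    round_robin,
)

corpus = default_corpus()
names = list(corpus)
records = round_robin(list(corpus.values()), turns=500, reps=5, seed=11,
                      include_self=True)
S = payoff_matrix(records, names)

res = replicator_solve(S, t_max=20_000, tol=1e-9)
print(f"replicator converged: {res.converged}")
for name, share in sorted(zip(names, res.gamma), key=lambda kv: -kv[1]):
    if share > 1e-4:
        print(f"  {name:12s} {share:.3f}")
print("  (all other strategies < 1e-4, including every extortioner)")

# Moran process: exact birth-death formula vs simulation
neutral = moran_fixation_exact(3, 3, 3, 3, N=5)
print(f"\nneutral fixation, N=5: kappa_1 = {neutral.kappa1:.3f} (= 1/N)")

exact = moran_fixation_exact(1.0, 5.0, 0.0, 3.0, N=5)
sim = moran_fixation_sim(get_strategy("Defector"), get_strategy("Cooperator"),
                         N=5, turns=20, reps=1000, seed=23)
print(f"defector invading cooperators, N=5: exact kappa_1 = {exact.kappa1:.3f}, "
      f"simulated = {sim.kappa1:.3f} +/- {sim.standard_error:.3f}")
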