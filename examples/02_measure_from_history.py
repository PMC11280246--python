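"""Measure a memory-one vector from an observed play history.

Uses the bundled 20-turn match of a chi-2 extortioner against Alternator.
Each prior-round state (CC, CD, DC, DD) is measured as the fraction of
its visits followed by a cooperation; the measured vector is then
projected to quantify how extortionate the observed behaviour was.
"""

from zdetect import count_transitions, measure_p, project, sse_trajectory, table1_history

history = table1_history()
counts = count_transitions(history)
print("visits per state (CC, CD, DC, DD):", counts.visits)
print("cooperations after each state:    ", counts.coops)

mv = measure_p(history)
print("measured p_hat:", mv.p_hat)  # (2/2, 1/5, 3/8, 0/4)

res = project(mv.p_hat)
print(f"projected: chi = {res.chi_hat:.4f}, SSE = {res.sse:.4f}")

# With only 19 transitions the measured vector is noisy, so the SSE is
# well above zero even though the underlying strategy is exactly
# extortionate.  The SSE of growing history prefixes shows the estimate
# settling as evidence accumulates:
traj = sse_trajectory(history)
for turn, sse in traj[:3] + traj[-3:]:
    print(f"  after {turn:2d} turns  SSE = {sse:.4f}")
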