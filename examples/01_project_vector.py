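"""Project memory-one vectors onto the extortion subspace.

The projection returns the best-fitting extortion coefficients, the
extortion factor chi = -beta/alpha, and the squared distance SSE from
the subspace.  chi > 1 with SSE ~ 0 is extortion; a large SSE proves a
vector is not extortionate.
"""

from zdetect import classify, project

for name, p in [
    ("chi-2 extortioner", (8 / 9, 1 / 2, 1 / 3, 0)),
    ("always cooperate", (1, 1, 1, 1)),
    ("Win-Stay Lose-Shift", (1, 0, 0, 1)),
    ("Generous Tit-For-Tat", (1, 1 / 3, 1, 1 / 3)),
]:
    res = project(p)
    print(
        f"{name:22s} chi = {res.chi_hat:8.4f}  SSE = {res.sse:.4f}  "
        f"-> {classify(res, sse_threshold=0.05)}"
    )

# The extortioner sits exactly on the subspace (SSE = 0) with chi = 2: it
# claims twice its opponent's surplus over the punishment payoff.  The
# cooperator is far away (SSE = 1.235) with a tiny chi: cooperation is the
# opposite of extortion.
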