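"""Match simulation and exact stationary analysis."""

import numpy as np
import pytest

from zdetect import (
    StrategySpec,
    default_corpus,
    get_strategy,
    play_match,
    project,
    stationary_scores,
    stationary_state,
)
from conftest import random_mixed_vectors


def test_defector_self_play_locks_mutual_defection():
    d = get_strategy("Defector")
    r = play_match(d, d, turns=100, seed=0)
    assert r.per_turn_x == r.per_turn_y == 1.0
    np.testing.assert_allclose(r.state_freq, (0, 0, 0, 1))
    assert r.winner == "tie"


def test_cooperator_vs_defector_scores():
    r = play_match(get_strategy("Cooperator"), get_strategy("Defector"),
                   turns=10, seed=0)
    assert (r.score_x, r.score_y) == (0.0, 50.0)
    assert r.winner == "y"


def test_identical_seeds_identical_histories():
    x, y = get_strategy("Joss"), get_strategy("GTFT")
    r1 = play_match(x, y, turns=500, seed=42)
    r2 = play_match(x, y, turns=500, seed=42)
    assert r1.history == r2.history
    assert r1.history != play_match(x, y, turns=500, seed=43).history


def test_noise_flips_moves():
    c = get_strategy("Cooperator")
    r = play_match(c, c, turns=2000, seed=7, noise=0.1)
    flips = sum(m == "D" for m in r.history.moves_x + r.history.moves_y)
    assert 0.05 < flips / 4000 < 0.15


def test_cycle_strategy_plays_its_sequence():
    cyc = StrategySpec("CCD-cycler", kind="cycle", cycle="CCD")
    r = play_match(cyc, get_strategy("Cooperator"), turns=7, seed=0)
    assert "".join(r.history.moves_x) == "CCDCCDC"


def test_turns_must_be_positive():
    c = get_strategy("Cooperator")
    with pytest.raises(ValueError, match="turns"):
        play_match(c, c, turns=0, seed=0)


def test_stationary_uniform_chain():
    v = stationary_state((0.5,) * 4, (0.5,) * 4)
    np.testing.assert_allclose(v, [0.25] * 4, atol=1e-12)


def test_stationary_scores_mutual_cooperation_limit():
    eps = 1e-9
    p = (1 - eps, 1 - eps, 1 - eps, 1 - eps)
    sx, sy = stationary_scores(p, p)
    assert sx == pytest.approx(3.0, abs=1e-6)
    assert sy == pytest.approx(3.0, abs=1e-6)


def test_extort2_enforces_score_relation():
    sx, sy = stationary_scores((8 / 9, 1 / 2, 1 / 3, 0), (0.5,) * 4)
    assert sx - 1 == pytest.approx(2 * (sy - 1), abs=1e-10)


def test_score_symmetry_under_role_swap(rng):
    for p, q in zip(random_mixed_vectors(rng, 20), random_mixed_vectors(rng, 20)):
        sx, sy = stationary_scores(p, q)
        sy2, sx2 = stationary_scores(q, p)
        assert sx == pytest.approx(sx2, abs=1e-9)
        assert sy == pytest.approx(sy2, abs=1e-9)


def test_near_defection_chain_concentrates_on_dd():
    eps = 1e-8
    v = stationary_state((eps,) * 4, (eps,) * 4)
    assert v[3] > 1 - 1e-6


def test_non_ergodic_chain_errors_without_fallback():
    tft = (1, 0, 1, 0)
    with pytest.raises(ValueError, match="not ergodic"):
        stationary_state(tft, tft)
    v = stationary_state(tft, tft, fallback_epsilon=1e-6)
    assert v.sum() == pytest.approx(1.0)


def test_simulation_matches_stationary_scores(rng):
    """Empirical per-turn scores over 1e5 turns agree with the exact
    Markov-chain scores to within 3 standard errors."""
    p = (0.8, 0.3, 0.6, 0.1)
    q = (0.6, 0.4, 0.5, 0.3)
    x = StrategySpec("px", vector=p)
    y = StrategySpec("qy", vector=q)
    sx, sy = stationary_scores(p, q)
    r = play_match(x, y, turns=100_000, seed=9)
    # per-turn payoff variance is bounded by the payoff range
    se = (5 - 0) / 2 / np.sqrt(100_000)
    assert abs(r.per_turn_x - sx) < 3 * se
    assert abs(r.per_turn_y - sy) < 3 * se


def test_bundled_extortioners_enforce_their_linear_relation(corpus, rng):
    """Every bundled extortionate strategy satisfies alpha*S_X + beta*S_Y +
    gamma = 0 against arbitrary fully-mixed opponents."""
    extortioners = [s for s in corpus.values() if s.zd_params is not None]
    assert len(extortioners) >= 3
    opponents = random_mixed_vectors(rng, 30)
    for spec in extortioners:
        alpha, beta, gamma = spec.zd_params
        for q in opponents:
            sx, sy = stationary_scores(spec.p, q)
            assert alpha * sx + beta * sy + gamma == pytest.approx(0.0, abs=1e-8)


def test_bundled_corpus_contents(corpus):
    expected = {"Cooperator", "Defector", "Alternator", "TitForTat", "WSLS",
                "GTFT", "Joss", "Extort-2", "ZD-Extort-3", "ZD-Extort-4",
                "ZD-GTFT-2"}
    assert expected <= set(corpus)
    assert corpus["Defector"].initial == "D"
    # the ZD-Extort family really sits on the extortion plane
    for name, chi in [("Extort-2", 2), ("ZD-Extort-3", 3), ("ZD-Extort-4", 4)]:
        res = project(corpus[name].p)
        assert res.sse < 1e-12
        assert res.chi_hat == pytest.approx(chi, abs=1e-9)


def test_unknown_strategy_name():
    with pytest.raises(KeyError, match="unknown strategy"):
        get_strategy("nope")
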