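"""Measuring memory-one vectors from observed play."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zdetect import (
    PlayHistory,
    count_transitions,
    get_strategy,
    measure_p,
    play_match,
    project,
    sse_trajectory,
)

moves = st.text(alphabet="CD", min_size=2, max_size=40)


def test_worked_example_counts(example_history):
    """The 20-turn extortioner-vs-Alternator match measures (2/2, 1/5, 3/8, 0/4)."""
    c = count_transitions(example_history, "focal")
    assert c.visits == (2, 5, 8, 4)
    assert c.coops == (2, 1, 3, 0)


def test_worked_example_measured_vector(example_history):
    mv = measure_p(example_history)
    np.testing.assert_allclose(mv.p_hat, (1.0, 0.2, 0.375, 0.0))
    assert mv.imputed_mask == (False, False, False, False)


def test_all_cooperate_history_only_visits_cc():
    h = PlayHistory.from_strings("CCC", "CCC")
    c = count_transitions(h)
    assert c.visits == (2, 0, 0, 0)
    assert c.coops == (2, 0, 0, 0)


def test_too_short_history_rejected():
    with pytest.raises(ValueError, match="at least 2 turns"):
        count_transitions(PlayHistory.from_strings("C", "D"))


@given(moves, moves)
@settings(derandomize=True, max_examples=100)
def test_perspective_symmetry_and_conservation(mx, my):
    n = min(len(mx), len(my))
    h = PlayHistory.from_strings(mx[:n], my[:n])
    focal_of_swap = count_transitions(h.swapped(), "focal")
    coplayer = count_transitions(h, "coplayer")
    assert focal_of_swap == coplayer
    assert sum(coplayer.visits) == n - 1


def test_unvisited_states_imputed_with_overall_rate():
    # against an unconditional cooperator the opponent never defects, so
    # the CD and DD rows of the extortioner's vector are unmeasurable and
    # get filled with its overall cooperation rate
    extort = get_strategy("Extort-2")
    coop = get_strategy("Cooperator")
    h = play_match(extort, coop, turns=2000, seed=11).history
    mv = measure_p(h)
    assert mv.imputed_mask[1] and mv.imputed_mask[3]
    assert not (mv.imputed_mask[0] or mv.imputed_mask[2])
    rate = h.moves_x.count("C") / len(h)
    assert mv.p_hat[1] == pytest.approx(rate)
    assert mv.p_hat[3] == pytest.approx(rate)


def test_imputation_none_raises_listing_states():
    h = PlayHistory.from_strings("CCC", "CCC")
    with pytest.raises(ValueError, match="CD.*DC.*DD"):
        measure_p(h, imputation="none")


def test_fixed_imputation_value():
    h = PlayHistory.from_strings("CCC", "CCC")
    mv = measure_p(h, imputation=0.25)
    np.testing.assert_allclose(mv.p_hat, (1.0, 0.25, 0.25, 0.25))


def test_all_defect_history():
    h = PlayHistory.from_strings("D" * 10, "D" * 10)
    mv = measure_p(h)
    # only DD visited (0/9); the rest imputed with coop rate 0
    np.testing.assert_allclose(mv.p_hat, (0, 0, 0, 0))
    assert mv.imputed_mask == (True, True, True, False)


def test_measurement_consistency_long_match():
    """Against a fully-mixed opponent every state recurs, so the measured
    vector converges to the true one; at n = 1e5 each component must lie
    within 3 binomial standard errors of truth."""
    from zdetect.engine import StrategySpec

    truth = (0.7, 0.4, 0.6, 0.2)
    x = StrategySpec("probe", vector=truth)
    y = StrategySpec("mixed", vector=(0.5, 0.5, 0.5, 0.5))
    h = play_match(x, y, turns=100_000, seed=5).history
    mv = measure_p(h)
    assert not any(mv.imputed_mask)
    for s in range(4):
        v = mv.counts.visits[s]
        se = np.sqrt(truth[s] * (1 - truth[s]) / v)
        assert abs(mv.p_hat[s] - truth[s]) < 3 * se


def test_sse_trajectory_final_matches_full_history(example_history):
    traj = sse_trajectory(example_history)
    assert len(traj) == 19
    assert traj[0][0] == 2 and traj[-1][0] == 20
    full = project(measure_p(example_history).p_hat).sse
    assert traj[-1][1] == pytest.approx(full, abs=1e-12)


def test_sse_trajectory_converges_for_on_plane_strategy():
    """An extortioner's measured SSE vanishes as the history grows."""
    from zdetect.engine import StrategySpec

    extort = get_strategy("Extort-2")
    mixed = StrategySpec("mixed", vector=(0.5, 0.5, 0.5, 0.5))
    h = play_match(extort, mixed, turns=20_000, seed=3).history
    traj = dict(sse_trajectory(h))
    assert traj[20_000] < 1e-3
    assert traj[20_000] < traj[50]


def test_constant_cooperator_trajectory_is_constant():
    h = PlayHistory.from_strings("C" * 10, "C" * 10)
    traj = sse_trajectory(h)
    sses = {round(s, 12) for _, s in traj}
    assert len(sses) == 1
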