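"""Replicator dynamics and Moran-process fixation."""

import numpy as np
import pytest

from zdetect import (
    get_strategy,
    moran_fixation_exact,
    moran_fixation_sim,
    replicator_solve,
)


def test_replicator_defection_dominates_one_shot_matrix():
    S = np.array([[3.0, 0.0], [5.0, 1.0]])  # row/col: Cooperator, Defector
    res = replicator_solve(S)
    assert res.converged
    np.testing.assert_allclose(res.gamma, [0, 1], atol=1e-6)


def test_replicator_constant_matrix_is_stationary():
    S = 2.0 * np.ones((4, 4))
    g0 = np.array([0.4, 0.3, 0.2, 0.1])
    res = replicator_solve(S, g0)
    assert res.converged
    np.testing.assert_allclose(res.gamma, g0, atol=1e-9)


def test_replicator_preserves_simplex():
    rng = np.random.default_rng(1)
    S = rng.random((5, 5)) * 4 + 0.5
    res = replicator_solve(S, t_max=100)
    assert res.gamma.sum() == pytest.approx(1.0, abs=1e-9)
    assert (res.gamma >= 0).all()


def test_replicator_rock_paper_scissors_does_not_converge():
    # zero-sum cyclic game: closed orbits around the interior fixed point
    S = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
    res = replicator_solve(S, np.array([0.5, 0.3, 0.2]), tol=1e-12, t_max=200)
    assert not res.converged
    assert (res.gamma > 0.01).all()  # still orbiting the interior


def test_replicator_dominated_strategy_goes_extinct():
    # strategy 0 strictly dominated by strategy 1
    S = np.array([[1.0, 0.5, 0.2], [2.0, 1.5, 1.2], [1.0, 1.0, 1.0]])
    res = replicator_solve(S, t_max=2000)
    assert res.gamma[0] < 1e-6


def test_replicator_restart_is_stable():
    S = np.array([[3.0, 0.0], [5.0, 1.0]])
    res = replicator_solve(S)
    res2 = replicator_solve(S, res.gamma)
    np.testing.assert_allclose(res2.gamma, res.gamma, atol=1e-8)


def test_moran_exact_neutral_is_one_over_N():
    for N in (2, 3, 5, 10, 50):
        est = moran_fixation_exact(2.0, 2.0, 2.0, 2.0, N)
        assert est.kappa1 == pytest.approx(1 / N, abs=1e-12)
        assert est.normalised == pytest.approx(1.0, abs=1e-10)


def test_moran_exact_N2_closed_form():
    a, b, c, d = 1.0, 4.0, 2.0, 3.0
    est = moran_fixation_exact(a, b, c, d, N=2)
    assert est.kappa1 == pytest.approx(b / (b + c), abs=1e-12)


def _fixation_by_chain_solve(a, b, c, d, N):
    """Independent oracle: solve the absorbing birth-death chain exactly.

    States j = 0..N count invaders; from j the chain moves to j+1 with
    probability p_j, to j-1 with q_j, else stays.  kappa_1 solves the
    linear system of first-step equations.
    """
    P_up = np.zeros(N + 1)
    P_dn = np.zeros(N + 1)
    for j in range(1, N):
        f = (a * (j - 1) + b * (N - j)) / (N - 1)
        g = (c * j + d * (N - j - 1)) / (N - 1)
        tot = j * f + (N - j) * g
        P_up[j] = (j * f / tot) * ((N - j) / N)
        P_dn[j] = ((N - j) * g / tot) * (j / N)
    A = np.zeros((N + 1, N + 1))
    rhs = np.zeros(N + 1)
    A[0, 0] = 1.0
    A[N, N] = 1.0
    rhs[N] = 1.0
    for j in range(1, N):
        A[j, j - 1] = P_dn[j]
        A[j, j] = -(P_up[j] + P_dn[j])
        A[j, j + 1] = P_up[j]
    kappa = np.linalg.solve(A, rhs)
    return kappa[1]


@pytest.mark.parametrize(
    "game, N",
    [
        ((1.0, 0.5, 3.0, 2.0), 10),  # strictly dominated invader
        ((3.0, 4.0, 1.0, 2.0), 8),  # advantaged invader
        ((2.0, 2.0, 2.0, 2.0), 6),  # neutral
    ],
)
def test_moran_exact_matches_chain_solve(game, N):
    est = moran_fixation_exact(*game, N)
    oracle = _fixation_by_chain_solve(*game, N)
    assert est.kappa1 == pytest.approx(oracle, abs=1e-10)


def test_moran_dominated_invader_below_neutral():
    est = moran_fixation_exact(1.0, 0.5, 3.0, 2.0, N=10)
    assert est.kappa1 < 1 / 10


def test_moran_cooperator_never_invades_defectors():
    # invader earns S = 0 against residents: fixation impossible
    est = moran_fixation_exact(3.0, 0.0, 5.0, 1.0, N=6)
    assert est.kappa1 == 0.0


def test_moran_sim_identical_strategies_is_neutral():
    tft = get_strategy("TitForTat")
    est = moran_fixation_sim(tft, tft, N=4, turns=20, reps=2000, seed=17)
    se = est.standard_error
    assert abs(est.kappa1 - 0.25) < 3 * se


def test_moran_sim_defector_invades_cooperators():
    """A lone defector among cooperators fixes more often than a neutral
    mutant; the simulated rate matches the exact formula on the
    deterministic per-turn scores."""
    defector = get_strategy("Defector")
    coop = get_strategy("Cooperator")
    N = 5
    est = moran_fixation_sim(defector, coop, N=N, turns=20, reps=1500, seed=23)
    exact = moran_fixation_exact(1.0, 5.0, 0.0, 3.0, N)
    assert est.kappa1 > 1 / N
    assert abs(est.kappa1 - exact.kappa1) < 3 * est.standard_error


def test_moran_invalid_population_size():
    with pytest.raises(ValueError):
        moran_fixation_exact(1, 1, 1, 1, N=1)
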