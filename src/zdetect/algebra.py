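"""Exact algebra of zero-determinant (ZD) and extortionate strategies.

A memory-one strategy is a vector p = (p1, p2, p3, p4) of cooperation
probabilities conditioned on the previous round's joint outcome, in the
fixed state order (CC, CD, DC, DD) where the first letter is the focal
player's own previous move.  A ZD strategy is one whose tilde-transformed
vector is a linear combination of the payoff vectors,

    p~ = alpha * S_x + beta * S_y + gamma * 1,

with S_x = (R, S, T, P), S_y = (R, T, S, P), which forces the linear
relation alpha*S_X + beta*S_Y + gamma = 0 between the two players'
stationary scores.  The extortionate subclass additionally requires
gamma = -P*(alpha + beta) and chi = -beta/alpha > 1, which guarantees
(S_X - P) = chi * (S_Y - P): the focal player claims a chi-fold share of
any surplus over the mutual-punishment payoff.

Eliminating (alpha, beta) shows that extortionate strategies form a
triangular plane in the (p2, p3, p1) space:

    p1 = [(R - P)(p2 + p3) - R + T + S - P] / (S + T - 2P),
    p4 = 0,
    p2 + p3 < 1,

with extortion factor

    chi = [p~2 (P - T) + p~3 (S - P)] / [p~2 (P - S) + p~3 (T - P)].

This module implements those conditions exactly; the statistical detector
(distance of an arbitrary vector from the plane) lives in
:mod:`zdetect.projection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PayoffParams",
    "DEFAULT_PAYOFFS",
    "ZDParams",
    "ExtortionDiagnostic",
    "as_memory_one",
    "transform_focal",
    "transform_coplayer",
    "invert_transform_focal",
    "is_extortionate",
    "chi_from_plane",
    "make_zd",
    "extortionate_vector",
]

#: State order used throughout the package: focal player's move first.
STATE_ORDER = ("CC", "CD", "DC", "DD")


@dataclass(frozen=True)
class PayoffParams:
    """The Prisoner's Dilemma payoff constants (R, S, T, P).

    R is the reward for mutual cooperation, S the sucker payoff for
    cooperating against a defection, T the temptation payoff for
    defecting against a cooperator and P the punishment for mutual
    defection.  The orderings ``T > R > P > S`` and ``2R > T + S``
    make defection the one-shot equilibrium while keeping mutual
    cooperation socially optimal.
    """

    R: float = 3.0
    S: float = 0.0
    T: float = 5.0
    P: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S; got "
                f"(R,S,T,P)=({self.R},{self.S},{self.T},{self.P})"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError("payoffs must satisfy 2R > T + S")
        if self.S + self.T - 2 * self.P == 0:
            raise ValueError(
                "degenerate payoffs: S + T - 2P = 0 (extortion plane undefined)"
            )

    @property
    def S_x(self) -> np.ndarray:
        """Focal player's payoff vector over states (CC, CD, DC, DD)."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)

    @property
    def S_y(self) -> np.ndarray:
        """Co-player's payoff vector over the focal state order."""
        return np.array([self.R, self.T, self.S, self.P], dtype=float)


DEFAULT_PAYOFFS = PayoffParams()


def as_memory_one(p) -> np.ndarray:
    """Validate and return a memory-one vector as a float array of length 4."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"memory-one vector must have 4 entries, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"memory-one probabilities must lie in [0, 1]; got {arr}")
    return arr


def transform_focal(p) -> np.ndarray:
    """Tilde transform of the focal player's vector: (p1-1, p2-1, p3, p4)."""
    p = as_memory_one(p)
    return np.array([p[0] - 1.0, p[1] - 1.0, p[2], p[3]])


def transform_coplayer(q) -> np.ndarray:
    """Tilde transform of the co-player's vector: (q1-1, q3, q2-1, q4).

    Components 2 and 3 are swapped relative to :func:`transform_focal`
    because the co-player sees each joint state with the roles reversed.
    """
    q = as_memory_one(q)
    return np.array([q[0] - 1.0, q[2], q[1] - 1.0, q[3]])


def invert_transform_focal(p_tilde) -> np.ndarray:
    """Invert :func:`transform_focal` (adds 1 back to the first two entries)."""
    pt = np.asarray(p_tilde, dtype=float)
    if pt.shape != (4,):
        raise ValueError("transformed vector must have 4 entries")
    return np.array([pt[0] + 1.0, pt[1] + 1.0, pt[2], pt[3]])


@dataclass(frozen=True)
class ZDParams:
    """The (alpha, beta, gamma) coefficients of a ZD linear relation."""

    alpha: float
    beta: float
    gamma: float

    @property
    def chi(self) -> float:
        """Extortion factor -beta/alpha (undefined for alpha = 0)."""
        if self.alpha == 0:
            raise ZeroDivisionError("chi undefined: alpha = 0")
        return -self.beta / self.alpha

    def is_extortionate(self, payoffs: PayoffParams = DEFAULT_PAYOFFS,
                        tol: float = 1e-9) -> bool:
        """Whether gamma = -P(alpha+beta) and chi > 1 hold."""
        if self.alpha == 0:
            return False
        return (
            abs(self.gamma + payoffs.P * (self.alpha + self.beta)) <= tol
            and self.chi > 1
        )


@dataclass(frozen=True)
class ExtortionDiagnostic:
    """Result of the exact extortion-plane membership test.

    ``failed`` lists which of the three algebraic conditions did not hold:
    ``"plane"`` (the p1 condition), ``"p4"`` (p4 = 0) or
    ``"disagreement"`` (p2 + p3 < 1).
    """

    extortionate: bool
    failed: tuple[str, ...] = field(default_factory=tuple)
    plane_residual: float = 0.0

    def __bool__(self) -> bool:
        return self.extortionate


def plane_p1(p2: float, p3: float, payoffs: PayoffParams = DEFAULT_PAYOFFS) -> float:
    """The value of p1 placing (p1, p2, p3, 0) on the extortion plane."""
    R, S, T, P = payoffs.R, payoffs.S, payoffs.T, payoffs.P
    return ((R - P) * (p2 + p3) - R + T + S - P) / (S + T - 2 * P)


def is_extortionate(p, payoffs: PayoffParams = DEFAULT_PAYOFFS,
                    tol: float = 1e-9) -> ExtortionDiagnostic:
    """Exact test of extortion-plane membership.

    Returns a truthy :class:`ExtortionDiagnostic` iff all three algebraic
    conditions hold to within ``tol``:  p1 on the plane, p4 = 0 and
    p2 + p3 < 1.  The tolerance only absorbs floating-point error; the
    statistical question (how *close* a vector is to the plane) is the
    business of :func:`zdetect.projection.project`.
    """
    p = as_memory_one(p)
    residual = p[0] - plane_p1(p[1], p[2], payoffs)
    failed = []
    if abs(residual) > tol:
        failed.append("plane")
    if abs(p[3]) > tol:
        failed.append("p4")
    if not (p[1] + p[2] < 1 - tol):
        failed.append("disagreement")
    return ExtortionDiagnostic(
        extortionate=not failed, failed=tuple(failed), plane_residual=residual
    )


def chi_from_plane(p, payoffs: PayoffParams = DEFAULT_PAYOFFS) -> float:
    """Extortion factor chi of a vector on (or assumed on) the plane.

    chi = [p~2 (P-T) + p~3 (S-P)] / [p~2 (P-S) + p~3 (T-P)].  Raises
    ``ZeroDivisionError`` when the denominator vanishes (chi undefined).
    """
    pt = transform_focal(p)
    R, S, T, P = payoffs.R, payoffs.S, payoffs.T, payoffs.P
    num = pt[1] * (P - T) + pt[2] * (S - P)
    den = pt[1] * (P - S) + pt[2] * (T - P)
    if den == 0:
        raise ZeroDivisionError("chi undefined: zero denominator in plane formula")
    return num / den


def make_zd(alpha: float, beta: float, gamma: float,
            payoffs: PayoffParams = DEFAULT_PAYOFFS) -> np.ndarray:
    """Construct the memory-one vector with p~ = alpha*S_x + beta*S_y + gamma.

    Raises ``ValueError`` if any resulting cooperation probability falls
    outside [0, 1]: such (alpha, beta, gamma) do not correspond to a
    feasible strategy, and clipping would silently corrupt the algebra.
    """
    p_tilde = alpha * payoffs.S_x + beta * payoffs.S_y + gamma * np.ones(4)
    p = invert_transform_focal(p_tilde)
    bad = [
        f"p{i + 1}={v:.6g}" for i, v in enumerate(p) if v < -1e-12 or v > 1 + 1e-12
    ]
    if bad:
        raise ValueError(
            f"infeasible ZD parameters (alpha={alpha}, beta={beta}, gamma={gamma}): "
            f"components outside [0,1]: {', '.join(bad)}"
        )
    return np.clip(p, 0.0, 1.0)


def extortionate_vector(chi: float, phi: float,
                        payoffs: PayoffParams = DEFAULT_PAYOFFS) -> np.ndarray:
    """Construct an extortionate strategy with extortion factor ``chi``.

    Uses the one-parameter family alpha = phi, beta = -phi*chi,
    gamma = -P*(alpha + beta); ``phi`` > 0 sets how far the vector sits
    from the plane's boundary, and must be small enough for feasibility
    (for the default payoffs, phi <= 1/(4*chi + 1)).
    """
    if chi <= 1:
        raise ValueError("extortion requires chi > 1")
    if phi <= 0:
        raise ValueError("phi must be positive")
    alpha = phi
    beta = -phi * chi
    gamma = -payoffs.P * (alpha + beta)
    return make_zd(alpha, beta, gamma, payoffs)
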