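"""Orthogonal projection onto the extortion subspace: the SSE detector.

Membership of the extortion plane is algebraically rigid: a measured
vector essentially never satisfies it exactly.  The detector instead asks
how *far* a vector is from the plane.  Writing the plane conditions as a
linear system C x = p~ in x = (alpha, beta), with

    C = [[R-P, R-P],
         [S-P, T-P],
         [T-P, S-P],
         [0,   0  ]],

the best-fitting coefficients are the least-squares solution
x* = (C^T C)^-1 C^T p~, the squared distance is SSE = ||C x* - p~||^2,
and the measured extortion factor is chi = -x2*/x1* (defined when
x1* != 0).  A small SSE with chi > 1 is the signature of extortionate
behaviour; a large SSE proves a strategy is not extortionate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebra import (
    DEFAULT_PAYOFFS,
    PayoffParams,
    invert_transform_focal,
    transform_focal,
)

__all__ = ["ProjectionResult", "build_C", "project", "project_tilde", "classify"]

#: |alpha_hat| below this is treated as alpha = 0 (chi undefined).
ALPHA_TOL = 1e-10


def build_C(payoffs: PayoffParams = DEFAULT_PAYOFFS) -> np.ndarray:
    """The 4x2 design matrix of the extortion-plane linear system.

    Rows follow the state order (CC, CD, DC, DD).  Raises ``ValueError``
    if the payoffs make C rank-deficient (the projection would then be
    ill-posed).
    """
    R, S, T, P = payoffs.R, payoffs.S, payoffs.T, payoffs.P
    C = np.array(
        [
            [R - P, R - P],
            [S - P, T - P],
            [T - P, S - P],
            [0.0, 0.0],
        ]
    )
    if np.linalg.matrix_rank(C) < 2:
        raise ValueError(f"design matrix is rank-deficient for payoffs {payoffs}")
    return C


@dataclass(frozen=True)
class ProjectionResult:
    """Best fit of a memory-one vector to the extortion subspace.

    Attributes
    ----------
    alpha_hat, beta_hat:
        The least-squares coefficients x* = (alpha, beta).
    sse:
        Squared Euclidean distance between p~ and its projection.
    chi_hat:
        Measured extortion factor -beta_hat/alpha_hat, or ``None`` when
        |alpha_hat| <= ALPHA_TOL (the ratio is then meaningless).
    nearest_tilde:
        C x*, the closest point of the subspace in tilde coordinates.
    """

    alpha_hat: float
    beta_hat: float
    sse: float
    chi_hat: float | None
    nearest_tilde: np.ndarray

    @property
    def chi_defined(self) -> bool:
        return self.chi_hat is not None

    @property
    def nearest_vector(self) -> np.ndarray:
        """The nearest subspace point mapped back to cooperation probabilities.

        May fall outside [0, 1]^4: the subspace extends beyond the feasible
        strategy cube.
        """
        return invert_transform_focal(self.nearest_tilde)


def project_tilde(p_tilde, payoffs: PayoffParams = DEFAULT_PAYOFFS) -> ProjectionResult:
    """Project an already tilde-transformed vector onto the extortion subspace."""
    pt = np.asarray(p_tilde, dtype=float)
    C = build_C(payoffs)
    CtC = C.T @ C
    x_star = np.linalg.solve(CtC, C.T @ pt)
    nearest = C @ x_star
    residual = nearest - pt
    sse_norm = float(residual @ residual)
    # second route: SSE = p~.p~ - p~.(C x*); both must agree
    sse_inner = float(pt @ pt - pt @ nearest)
    if abs(sse_norm - sse_inner) > 1e-10 * max(1.0, sse_norm):
        raise AssertionError(
            f"inconsistent SSE formulations: {sse_norm!r} vs {sse_inner!r}"
        )
    sse = max(sse_norm, 0.0)
    alpha_hat, beta_hat = float(x_star[0]), float(x_star[1])
    chi_hat = -beta_hat / alpha_hat if abs(alpha_hat) > ALPHA_TOL else None
    return ProjectionResult(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        sse=sse,
        chi_hat=chi_hat,
        nearest_tilde=nearest,
    )


def project(p, payoffs: PayoffParams = DEFAULT_PAYOFFS) -> ProjectionResult:
    """Project a memory-one vector p onto the extortion subspace.

    Applies the focal tilde transform and solves the normal equations in
    closed form.  Well-posed for every p since C has rank 2.
    """
    return project_tilde(transform_focal(p), payoffs)


def classify(result: ProjectionResult, sse_threshold: float = 0.05) -> str:
    """Label a projection as 'extortionate', 'generous-ZD-like' or 'not-ZD'.

    A vector close to the subspace (SSE <= threshold) acts as a ZD
    strategy: extortionate when chi > 1, generous when 0 < chi <= 1.
    Everything else — including a near-subspace fit whose chi is
    undefined (alpha ~ 0) — is 'not-ZD'.  The threshold is a modelling
    choice; reports should always carry the raw SSE and chi as well.
    """
    if result.sse <= sse_threshold and result.chi_hat is not None:
        if result.chi_hat > 1:
            return "extortionate"
        if result.chi_hat > 0:
            return "generous-ZD-like"
    return "not-ZD"
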