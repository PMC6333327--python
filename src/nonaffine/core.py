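"""Best-affine fit, projection operator and the non-affine parameter chi.

For a neighborhood Omega_i the stacked relative displacements
Delta_ij = u_j - u_i = (r_j - R_j) - (r_i - R_i) form an n_omega*3 column
vector Delta.  The non-affine parameter is the least-squares error of the
best homogeneous deformation D:

    chi_i = min_D sum_j [ Delta_ij - D (R_j - R_i) ]^2

which equals Delta^T P Delta with the projector onto the non-affine
subspace P = I - R (R^T R)^{-1} R^T.  Both routes are implemented —
:func:`chi_direct` solves the normal equations and serves as the
independent oracle for the projection route :func:`chi_projected`.
chi carries units of Angstrom^2 and is an unnormalized per-neighborhood
sum; pass ``per_atom=True`` where offered to divide by n_omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import ConformationEnsemble, ReferenceStructure
from .neighborhoods import D, Neighborhood

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodDisplacement:
    """Stacked relative displacement vector Delta for one frame and one neighborhood."""

    delta: np.ndarray  # (n_omega * 3,), member order as in the Neighborhood
    frame_index: int = 0

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float).ravel()
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("displacement vector must be finite")


@dataclass
class ProjectionOperator:
    """Symmetric idempotent projector onto the non-affine subspace.

    ``basis`` is an orthonormal basis Q of the affine column space of R,
    so that P = I - Q Q^T; it is kept for O(n*9) chi evaluation.
    """

    P: np.ndarray
    basis: np.ndarray | None = None


@dataclass
class AffineFit:
    """Best homogeneous deformation D and its residual (= chi, A^2)."""

    D: np.ndarray  # (3, 3)
    residual: float


def displacements(
    ref: ReferenceStructure, frame: np.ndarray, nb: Neighborhood, frame_index: int = 0
) -> NeighborhoodDisplacement:
    """Delta for one frame: member displacements relative to the center's."""
    frame = np.asarray(frame, dtype=float)
    u = frame - ref.positions
    delta = u[nb.member_indices] - u[nb.center_index]
    return NeighborhoodDisplacement(delta=delta.ravel(), frame_index=frame_index)


def build_projection(nb: Neighborhood) -> ProjectionOperator:
    """P = I - R (R^T R)^{-1} R^T via an orthonormal basis of col(R)."""
    R = nb.R_matrix
    Q, _ = np.linalg.qr(R)  # reduced QR; R has full column rank by construction
    m = R.shape[0]
    P = np.eye(m) - Q @ Q.T
    P = 0.5 * (P + P.T)
    return ProjectionOperator(P=P, basis=Q)


def chi_projected(disp: NeighborhoodDisplacement, proj: ProjectionOperator) -> float:
    """chi = Delta^T P Delta (A^2); tiny negative round-off is clamped to 0."""
    delta = disp.delta
    if delta.shape[0] != proj.P.shape[0]:
        raise ValueError(
            f"dimension mismatch: Delta has {delta.shape[0]} components, "
            f"P is {proj.P.shape[0]} x {proj.P.shape[1]}"
        )
    chi = float(delta @ proj.P @ delta)
    if chi < 0:
        if chi < -1e-8 * max(1.0, float(delta @ delta)):
            raise ValueError(f"chi significantly negative ({chi:g}): invalid projector")
        logger.debug("clamping tiny negative chi %.3g to 0", chi)
        chi = 0.0
    return chi


def chi_direct(disp: NeighborhoodDisplacement, nb: Neighborhood) -> AffineFit:
    """Solve the normal equations (R^T R) vec(D) = R^T Delta explicitly.

    Independent of the projection route; the returned residual equals chi.
    """
    R = nb.R_matrix
    delta = disp.delta
    if delta.shape[0] != R.shape[0]:
        raise ValueError(
            f"dimension mismatch: Delta has {delta.shape[0]} components, "
            f"R has {R.shape[0]} rows"
        )
    gram = R.T @ R
    vec_d = scipy.linalg.solve(gram, R.T @ delta, assume_a="pos")
    resid_vec = delta - R @ vec_d
    return AffineFit(D=vec_d.reshape(D, D), residual=float(resid_vec @ resid_vec))


def displacement_matrix(
    ref: ReferenceStructure, ensemble: ConformationEnsemble, nb: Neighborhood
) -> np.ndarray:
    """All frames' Delta vectors stacked as a (T, n_omega*3) matrix."""
    u = ensemble.frames - ref.positions[None, :, :]
    delta = u[:, nb.member_indices, :] - u[:, [nb.center_index], :]
    return delta.reshape(ensemble.n_frames, nb.dof)


def chi_series(
    ref: ReferenceStructure,
    ensemble: ConformationEnsemble,
    nb: Neighborhood,
    proj: ProjectionOperator | None = None,
    per_atom: bool = False,
) -> np.ndarray:
    """chi at every frame for one neighborhood.

    Uses chi = |Delta|^2 - |Q^T Delta|^2 with Q the orthonormal affine
    basis, algebraically identical to Delta^T P Delta but O(n*9) per frame.
    """
    if proj is None or proj.basis is None:
        proj = build_projection(nb)
    deltas = displacement_matrix(ref, ensemble, nb)
    total = np.einsum("tm,tm->t", deltas, deltas)
    affine = deltas @ proj.basis
    chi = total - np.einsum("tk,tk->t", affine, affine)
    np.clip(chi, 0.0, None, out=chi)
    if per_atom:
        chi = chi / nb.n_members
    return chi
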