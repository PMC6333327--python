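"""Coarse-graining neighborhoods and the reference-geometry matrix R.

Each analysed atom i carries a neighborhood Omega_i: the set of atoms
within a fixed radius of i in the reference structure (hydrogens excluded
by default, the center excluded always).  The local affine subspace is
spanned by the columns of the (n_omega*3) x 9 matrix R whose row block for
member j is  R[j*3 + a, 3*g + g'] = delta(a, g) * (R_j - R_i)[g'],
i.e. the stacked displacements R @ vec(D) produced by every homogeneous
deformation D of the neighborhood about its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import ReferenceStructure

D = 3  # spatial dimension; the affine subspace has dimension D*D = 9

DEFAULT_MIN_SIZE = 10
DEFAULT_TARGET_N = (50, 100)  # heavy atoms per neighborhood


class DegenerateNeighborhoodError(ValueError):
    """Neighborhood has too few members for a meaningful affine fit."""


class CollinearityError(ValueError):
    """Neighborhood geometry does not span all 9 affine degrees of freedom."""


def build_r_matrix(rel_positions: np.ndarray) -> np.ndarray:
    """The (n*3) x 9 affine design matrix from member positions relative to the center."""
    rel = np.asarray(rel_positions, dtype=float)
    n = rel.shape[0]
    R = np.zeros((n, D, D, D))
    for a in range(D):
        R[:, a, a, :] = rel
    return R.reshape(n * D, D * D)


@dataclass
class Neighborhood:
    """Atom i, its member set Omega_i and the derived affine design matrix."""

    center_index: int
    member_indices: np.ndarray  # ascending, excludes center
    radius: float
    R_matrix: np.ndarray  # (n_omega*3, 9)
    condition_number: float = field(default=np.nan)

    @property
    def n_members(self) -> int:
        return len(self.member_indices)

    @property
    def dof(self) -> int:
        """Dimension of the stacked displacement vector, n_omega * 3."""
        return self.n_members * D


def build_neighborhood(
    ref: ReferenceStructure,
    center: int,
    radius: float,
    heavy_only: bool = True,
    min_size: int = DEFAULT_MIN_SIZE,
    max_condition: float = 1e8,
    k_nearest: int | None = None,
    _tree: cKDTree | None = None,
) -> Neighborhood:
    """Build Omega_i for one center atom from the reference geometry.

    Members are all atoms (heavy atoms if ``heavy_only``) within ``radius``
    of the center, sorted by atom index, center excluded.  Alternatively
    ``k_nearest`` selects a fixed number of nearest atoms (``radius`` then
    only annotates the result).  Raises
    :class:`DegenerateNeighborhoodError` if fewer than ``min_size`` members
    remain and :class:`CollinearityError` if the member geometry is
    rank-deficient or ill-conditioned (condition number of R^T R above
    ``max_condition``).
    """
    if not 0 <= center < ref.n_atoms:
        raise IndexError(f"center index {center} out of range")
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions = ref.positions
    if k_nearest is not None:
        mask = ref.heavy_mask if heavy_only else np.ones(ref.n_atoms, dtype=bool)
        candidates = np.nonzero(mask)[0]
        candidates = candidates[candidates != center]
        if len(candidates) < k_nearest:
            raise DegenerateNeighborhoodError(
                f"only {len(candidates)} candidate atoms for k_nearest={k_nearest}"
            )
        d = np.linalg.norm(positions[candidates] - positions[center], axis=1)
        members = np.sort(candidates[np.argsort(d, kind="stable")[:k_nearest]])
    else:
        tree = _tree if _tree is not None else cKDTree(positions)
        members = np.array(
            sorted(tree.query_ball_point(positions[center], radius)), dtype=int
        )
        members = members[members != center]
        if heavy_only:
            members = members[ref.heavy_mask[members]]
    if len(members) < min_size:
        raise DegenerateNeighborhoodError(
            f"neighborhood of atom {center} has {len(members)} members "
            f"(minimum {min_size}) at radius {radius:g} A"
        )
    rel = positions[members] - positions[center]
    R = build_r_matrix(rel)
    s = np.linalg.svd(R, compute_uv=False)
    if s[-1] <= s[0] * 1e-12:
        raise CollinearityError(
            f"neighborhood of atom {center}: member geometry spans fewer than "
            f"{D * D} affine degrees of freedom"
        )
    cond = (s[0] / s[-1]) ** 2  # condition number of R^T R
    if cond > max_condition:
        raise CollinearityError(
            f"neighborhood of atom {center}: R^T R condition number "
            f"{cond:.3g} exceeds {max_condition:.3g}"
        )
    return Neighborhood(
        center_index=int(center),
        member_indices=members,
        radius=float(radius),
        R_matrix=R,
        condition_number=float(cond),
    )


def neighborhood_sizes(
    ref: ReferenceStructure, radius: float, heavy_only: bool = True
) -> np.ndarray:
    """Member count of every (heavy) atom's neighborhood at the given radius."""
    mask = ref.heavy_mask if heavy_only else np.ones(ref.n_atoms, dtype=bool)
    pts = ref.positions[mask]
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radius, return_length=True)
    return counts - 1  # center excluded


def calibrate_radius(
    ref: ReferenceStructure,
    target_n=DEFAULT_TARGET_N,
    heavy_only: bool = True,
    grid_step: float = 0.1,
    max_radius: float = 50.0,
) -> float:
    """Smallest radius on a 0.1 A grid whose median neighborhood size hits the target.

    The default target of 50-100 heavy atoms makes the neighborhood small
    enough to stay local but large enough to average out single-atom noise.
    """
    lo, hi = int(min(target_n)), int(max(target_n))
    if lo > hi or lo < 1:
        raise ValueError(f"empty or invalid target range {target_n!r}")
    n_avail = int(ref.heavy_mask.sum()) - 1 if heavy_only else ref.n_atoms - 1
    if n_avail < lo:
        raise ValueError(
            f"target of at least {lo} members is unreachable: only {n_avail} "
            "candidate atoms exist"
        )
    radii = np.arange(grid_step, max_radius + grid_step / 2, grid_step)
    # median count is non-decreasing in radius: binary search the grid
    left, right = 0, len(radii) - 1
    if np.median(neighborhood_sizes(ref, radii[right], heavy_only)) < lo:
        raise ValueError(
            f"median neighborhood size stays below {lo} up to radius {max_radius} A"
        )
    while left < right:
        mid = (left + right) // 2
        if np.median(neighborhood_sizes(ref, radii[mid], heavy_only)) >= lo:
            right = mid
        else:
            left = mid + 1
    radius = float(radii[left])
    median = float(np.median(neighborhood_sizes(ref, radius, heavy_only)))
    if median > hi:
        raise ValueError(
            f"no grid radius reaches the target: at {radius:g} A the median "
            f"size jumps to {median:g} (> {hi})"
        )
    return radius


def build_neighborhoods(
    ref: ReferenceStructure,
    centers,
    radius: float,
    heavy_only: bool = True,
    min_size: int = DEFAULT_MIN_SIZE,
    max_condition: float = 1e8,
) -> tuple[dict, dict]:
    """Build neighborhoods for many centers.

    Returns ``(neighborhoods, failures)`` where ``failures`` maps the center
    index of every degenerate/collinear neighborhood to the error message;
    such sites are excluded from aggregate statistics downstream.
    """
    neighborhoods: dict[int, Neighborhood] = {}
    failures: dict[int, str] = {}
    tree = cKDTree(ref.positions)
    for center in centers:
        try:
            neighborhoods[int(center)] = build_neighborhood(
                ref, int(center), radius, heavy_only, min_size, max_condition,
                _tree=tree,
            )
        except (DegenerateNeighborhoodError, CollinearityError) as exc:
            failures[int(center)] = str(exc)
    return neighborhoods, failures
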