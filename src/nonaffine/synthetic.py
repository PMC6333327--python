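"""Synthetic references and ensembles with known affine/non-affine content.

Every generator is deterministic given its seed and produces structures in
the containers used by the rest of the package, so each claim about chi —
annihilation of homogeneous deformations, planted-soft-mode recovery, the
gap/susceptibility link, the fluctuation-response relation — is testable
without external data.

Geometries
----------
``lattice``  : cubic lattice, for closed-form neighbor counts.
``cloud``    : uniform points at protein-like heavy-atom density
               (~0.1 atoms/A^3 by default).
``helix``    : a helical chain of 8-atom pseudo-residues whose spatial and
               sequence order agree, emulating protein residue granularity
               for residue-level correlation/allostery tests.

Planted-mode amplitudes are specified as the per-atom RMS displacement of
the mode relative to the isotropic noise sigma: a unit-norm stacked mode
spread over n_omega members displaces each by ~1/sqrt(n_omega), so the
stacked amplitude std is  amp_rms * sqrt(n_omega).  "10:1 over noise" then
means each member atom moves ten times as far along the mode as the noise
moves it, independent of neighborhood size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import build_projection
from .io import ConformationEnsemble, ReferenceStructure
from .neighborhoods import Neighborhood

RESIDUE_SIZE = 8  # atoms per pseudo-residue


def _finalize_reference(positions: np.ndarray, source: str) -> ReferenceStructure:
    n = positions.shape[0]
    atom_name = np.array(
        ["CA" if i % RESIDUE_SIZE == 0 else f"C{i % RESIDUE_SIZE + 1}" for i in range(n)]
    )
    return ReferenceStructure(
        positions=positions,
        element=np.full(n, "C"),
        atom_name=atom_name,
        residue_id=np.arange(n) // RESIDUE_SIZE + 1,
        residue_name=np.full(n, "ALA"),
        chain_id=np.full(n, "A"),
        metadata={"source": source, "reference_kind": "synthetic"},
    )


def lattice_reference(shape=(5, 5, 5), spacing: float = 1.5) -> ReferenceStructure:
    """Cubic lattice of heavy atoms; neighbor counts have closed forms."""
    nx, ny, nz = shape
    grid = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return _finalize_reference(grid * float(spacing), f"lattice{shape}")


def cloud_reference(
    n_atoms: int = 1000, density: float = 0.1, seed: int = 0
) -> ReferenceStructure:
    """Uniform cloud at a given heavy-atom density (atoms/A^3) in a cube."""
    if n_atoms < 20:
        raise ValueError("need at least 20 atoms")
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    side = (n_atoms / density) ** (1 / 3)
    positions = rng.uniform(0.0, side, size=(n_atoms, 3))
    return _finalize_reference(positions, f"cloud(n={n_atoms},rho={density})")


def helix_reference(
    n_residues: int = 60,
    helix_radius: float = 2.3,
    rise_per_residue: float = 1.5,
    twist_deg: float = 100.0,
    jitter: float = 1.2,
    seed: int = 0,
) -> ReferenceStructure:
    """Helical chain of 8-atom pseudo-residues.

    Defaults mimic an alpha-helix backbone (2.3 A radius, 1.5 A rise,
    100 degrees twist per residue) with side-chain-like jitter around each
    backbone point; local density comes out near protein-like (~0.1/A^3)
    and sequence-distant residues are spatially distant (1.5 A per residue
    along the axis).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    k = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * k
    backbone = np.stack(
        [helix_radius * np.cos(theta), helix_radius * np.sin(theta), rise_per_residue * k],
        axis=1,
    )
    positions = np.repeat(backbone, RESIDUE_SIZE, axis=0) + rng.normal(
        0.0, jitter, size=(n_residues * RESIDUE_SIZE, 3)
    )
    return _finalize_reference(positions, f"helix(n_res={n_residues})")


def make_reference(geometry: str = "cloud", seed: int = 0, **kwargs) -> ReferenceStructure:
    """Dispatch on geometry name: 'lattice' | 'cloud' | 'helix'."""
    if geometry == "lattice":
        return lattice_reference(**kwargs)
    if geometry == "cloud":
        return cloud_reference(seed=seed, **kwargs)
    if geometry == "helix":
        return helix_reference(seed=seed, **kwargs)
    raise ValueError(f"unknown geometry {geometry!r}")


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def affine_ensemble(
    ref: ReferenceStructure, d_schedule: np.ndarray, center: np.ndarray | None = None
) -> ConformationEnsemble:
    """Frames produced by homogeneous deformations: r_t = c + D_t (R - c).

    Any such ensemble lies entirely in every neighborhood's affine
    subspace, so chi vanishes identically at every site and frame.
    """
    d_schedule = np.asarray(d_schedule, dtype=float)
    if d_schedule.ndim != 3 or d_schedule.shape[1:] != (3, 3):
        raise ValueError("d_schedule must be (T, 3, 3)")
    if np.any(np.abs(np.linalg.det(d_schedule)) < 1e-12):
        raise ValueError("every D_t must be invertible")
    if center is None:
        center = ref.positions.mean(axis=0)
    rel = ref.positions - center
    frames = center + np.einsum("tab,nb->tna", d_schedule, rel)
    return ConformationEnsemble(frames=frames)


def rotation_schedule(angles_deg, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Per-frame rotation matrices about a fixed axis (angles in degrees)."""
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(
        np.deg2rad(np.asarray(angles_deg, dtype=float))[:, None] * axis
    ).as_matrix()


def nonaffine_unit_mode(
    nb: Neighborhood, seed: int = 0, support: np.ndarray | None = None
) -> np.ndarray:
    """A unit-norm stacked vector in the non-affine subspace of a neighborhood.

    A random vector (optionally restricted to the member atoms in
    ``support``) is projected with P and normalized, guaranteeing
    P e = e to machine precision.  Restricting the support concentrates the
    mode on chosen atoms, e.g. one pseudo-residue.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(nb.dof)
    if support is not None:
        keep = np.isin(nb.member_indices, np.asarray(support, dtype=int))
        if not keep.any():
            raise ValueError("support contains no member of the neighborhood")
        z = z * np.repeat(keep, 3)
    proj = build_projection(nb)
    e = z - proj.basis @ (proj.basis.T @ z)
    norm = np.linalg.norm(e)
    if norm < 1e-12:
        raise ValueError("support lies entirely in the affine subspace")
    return e / norm


@dataclass
class PlantedMode:
    """A non-affine mode planted at one site.

    ``per_atom_rms`` is the RMS displacement of a member atom along the
    mode, in units of A (compare with the isotropic noise sigma).  Modes
    sharing an ``amplitude_group`` share the same per-frame amplitude
    series, creating correlated non-affine activity at distant sites.
    """

    neighborhood: Neighborhood
    vector: np.ndarray
    per_atom_rms: float
    amplitude_group: object = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (self.neighborhood.dof,):
            raise ValueError("mode vector length must equal the neighborhood dof")
        proj = build_projection(self.neighborhood)
        if np.linalg.norm(proj.P @ self.vector - self.vector) > 1e-8:
            raise ValueError("planted mode is not in the non-affine subspace")

    @property
    def stacked_std(self) -> float:
        return self.per_atom_rms * np.sqrt(self.neighborhood.n_members)


def mode_ensemble(
    ref: ReferenceStructure,
    modes: list[PlantedMode],
    noise_sigma: float,
    T: int,
    seed: int = 0,
) -> tuple[ConformationEnsemble, dict]:
    """Reference + planted non-affine modes + isotropic Gaussian noise.

    Frame t displaces each mode's member atoms by a_t * e (a_t Gaussian
    with the mode's stacked std) and every atom by N(0, noise_sigma^2)
    isotropic noise.  Returns the ensemble and a dict with the amplitude
    series per group for planted-signal tests.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[object, np.ndarray] = {}
    for k, mode in enumerate(modes):
        key = mode.amplitude_group if mode.amplitude_group is not None else ("_solo", k)
        if key not in groups:
            groups[key] = rng.standard_normal(T)
    frames = np.broadcast_to(ref.positions, (T, ref.n_atoms, 3)).copy()
    for k, mode in enumerate(modes):
        key = mode.amplitude_group if mode.amplitude_group is not None else ("_solo", k)
        amps = groups[key] * mode.stacked_std
        disp = mode.vector.reshape(-1, 3)
        frames[:, mode.neighborhood.member_indices, :] += amps[:, None, None] * disp
    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    info = {
        "amplitudes": {key: groups[key] for key in groups},
        "modes": modes,
        "noise_sigma": noise_sigma,
    }
    return ConformationEnsemble(frames=frames), info


def graded_softness_ensemble(
    ref: ReferenceStructure,
    neighborhoods: list[Neighborhood],
    rms_range: tuple[float, float] = (1.5, 15.0),
    noise_sigma: float = 1.0,
    T: int = 400,
    seed: int = 0,
) -> tuple[ConformationEnsemble, dict]:
    """One planted mode per site with geometrically graded amplitude.

    Emulates a protein with regions of graded softness: sites with larger
    planted amplitude have both a larger spectral gap and a larger NAP
    susceptibility, the joint trend the gap/susceptibility analysis tests.
    Grading is geometric (log-uniform) over an order of magnitude — local
    compliance in heterogeneous matter varies on a multiplicative scale,
    and log-uniform grading separates sites equally in both the gap and
    the susceptibility ranking.
    """
    lo, hi = rms_range
    amps = np.geomspace(lo, hi, len(neighborhoods)) * noise_sigma
    modes = [
        PlantedMode(nb, nonaffine_unit_mode(nb, seed=seed + 7 * k), per_atom_rms=amps[k])
        for k, nb in enumerate(neighborhoods)
    ]
    ensemble, info = mode_ensemble(ref, modes, noise_sigma, T, seed=seed + 10_000)
    info["per_atom_rms"] = amps
    return ensemble, info


def field_ensemble(
    ref: ReferenceStructure,
    nb: Neighborhood,
    h: float,
    base_sigma: float,
    T: int,
    seed: int = 0,
) -> ConformationEnsemble:
    """Gaussian neighborhood displacements under a conjugate NAP field h.

    Delta is drawn from the Boltzmann weight of the quadratic energy
    (1/2) sigma^-2 |Delta|^2 - h Delta^T P Delta, i.e. a Gaussian with
    variance sigma^2 in the affine subspace and sigma^2/(1 - 2 h sigma^2)
    along every non-affine direction.  Stable only for h < 1/(2 sigma^2).
    The field mimics a ligand coupling linearly to chi: switching h on
    shifts <chi> in proportion to the zero-field susceptibility.
    """
    if base_sigma <= 0:
        raise ValueError("base_sigma must be positive")
    h_max = 1.0 / (2.0 * base_sigma**2)
    if h >= h_max:
        raise ValueError(
            f"field h={h:g} at or above the stability limit 1/(2 sigma^2) = {h_max:g}"
        )
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, base_sigma, size=(T, nb.dof))
    proj = build_projection(nb)
    scale = 1.0 / np.sqrt(1.0 - 2.0 * h * base_sigma**2)
    pz = z - (z @ proj.basis) @ proj.basis.T
    delta = z + (scale - 1.0) * pz
    frames = np.broadcast_to(ref.positions, (T, ref.n_atoms, 3)).copy()
    frames[:, nb.member_indices, :] += delta.reshape(T, nb.n_members, 3)
    return ConformationEnsemble(frames=frames)


def field_mean_chi(nb: Neighborhood, base_sigma: float, h: float) -> float:
    """Closed-form <chi> under the conjugate field.

    Each of the n_omega*3 - 9 non-affine directions contributes
    sigma^2 / (1 - 2 h sigma^2); the affine block contributes nothing.
    """
    m = nb.dof - 9
    return m * base_sigma**2 / (1.0 - 2.0 * h * base_sigma**2)


def random_correlation(dim: int, n_frames: int, seed: int = 0) -> np.ndarray:
    """Sample covariance of i.i.d. N(0, 1) vectors: the Wishart/MP null case."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_frames, dim))
    return Z.T @ Z / n_frames


def isotropic_ensemble(
    ref: ReferenceStructure, sigma: float, T: int, seed: int = 0
) -> ConformationEnsemble:
    """Reference plus i.i.d. isotropic Gaussian displacements on every atom."""
    rng = np.random.default_rng(seed)
    frames = ref.positions[None, :, :] + rng.normal(
        0.0, sigma, size=(T, ref.n_atoms, 3)
    )
    return ConformationEnsemble(frames=frames)
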