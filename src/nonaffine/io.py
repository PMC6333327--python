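"""Structure and ensemble I/O.

Reads a reference structure from a PDB file and a conformational ensemble
from either a multi-model PDB or a binary trajectory (XTC/TRR/DCD) plus a
matching topology.  All coordinates are kept in Angstrom internally;
nm-based trajectory formats are converted on read.  Atom indexing is
0-based internally while file outputs carry the source residue ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb


class FormatError(ValueError):
    """Raised for unparseable or inconsistent input files."""


class SelectionError(ValueError):
    """Raised when an atom selection is malformed or empty."""


# Trajectory formats whose native length unit is nm (converted to A on read).
_NM_FORMATS = {".xtc", ".trr"}
_BINARY_TRAJ = {".xtc", ".trr", ".dcd"}


@dataclass
class ReferenceStructure:
    """Fixed reference positions R_i and per-atom metadata.

    Parameters
    ----------
    positions : (N, 3) float array, Angstrom
    element : (N,) str array of chemical elements (upper case)
    atom_name, residue_name, chain_id : (N,) str arrays
    residue_id : (N,) int array, as in the source file
    """

    positions: np.ndarray
    element: np.ndarray
    atom_name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.n_atoms < 1:
            raise ValueError("reference must contain at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("reference positions must be finite")
        for name in ("element", "atom_name", "residue_id", "residue_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (self.n_atoms,):
                raise ValueError(f"{name} must have length {self.n_atoms}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms, derived from the element field."""
        elements = np.char.upper(self.element.astype(str))
        return (elements != "H") & (elements != "D")

    def residue_ids_unique(self) -> np.ndarray:
        """Residue ids in order of first appearance."""
        _, first = np.unique(self.residue_id, return_index=True)
        return self.residue_id[np.sort(first)]


@dataclass
class ConformationEnsemble:
    """A T x N x 3 stack of frames sharing the reference atom order."""

    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (T, N, 3)")
        if self.n_frames < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def _fill_elements(atoms: struc.AtomArray) -> np.ndarray:
    """Element symbols with a name-based fallback for blank element columns."""
    elements = np.char.upper(np.char.strip(atoms.element.astype(str)))
    blank = elements == ""
    if np.any(blank):
        for i in np.nonzero(blank)[0]:
            name = atoms.atom_name[i].strip()
            # first alphabetic character of the atom name, e.g. "1HB" -> H
            match = re.search(r"[A-Za-z]", name)
            elements[i] = match.group(0).upper() if match else "X"
    return elements


def _atoms_to_reference(atoms: struc.AtomArray, meta: dict) -> ReferenceStructure:
    return ReferenceStructure(
        positions=np.asarray(atoms.coord, dtype=float),
        element=_fill_elements(atoms),
        atom_name=atoms.atom_name.astype(str),
        residue_id=atoms.res_id.astype(int),
        residue_name=atoms.res_name.astype(str),
        chain_id=atoms.chain_id.astype(str),
        metadata=meta,
    )


def load_reference(path, model_index: int = 0) -> ReferenceStructure:
    """Load one model of a PDB file as the fixed reference structure.

    ``model_index`` is 0-based.  The default (first model) corresponds to
    using the crystal/native structure as reference; a time-averaged
    structure may be passed instead by writing it to a PDB first.
    """
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure()
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path!r}: {exc}") from exc
    if not 0 <= model_index < stack.stack_depth():
        raise IndexError(
            f"model_index {model_index} out of range: file has "
            f"{stack.stack_depth()} model(s)"
        )
    atoms = stack[model_index]
    meta = {"source": str(path), "model_index": model_index, "reference_kind": "crystal"}
    return _atoms_to_reference(atoms, meta)


def _probe_trajectory_atoms(path: str, suffix: str) -> int:
    """Atom count stored in a binary trajectory, for mismatch diagnostics."""
    from mdtraj.formats import DCDTrajectoryFile, TRRTrajectoryFile, XTCTrajectoryFile

    readers = {".xtc": XTCTrajectoryFile, ".trr": TRRTrajectoryFile, ".dcd": DCDTrajectoryFile}
    with readers[suffix](path) as fh:
        out = fh.read(1)
    xyz = out[0] if isinstance(out, tuple) else out
    return int(xyz.shape[1])


def load_ensemble(topology, trajectory=None) -> ConformationEnsemble:
    """Load a conformational ensemble.

    With only ``topology`` given, it must be a multi-model PDB whose models
    are the frames.  With ``trajectory`` given, the topology provides the
    atom set and the trajectory the frames; XTC/TRR store nm and are
    converted to Angstrom.
    """
    if trajectory is None:
        try:
            pdb_file = pdb.PDBFile.read(str(topology))
            stack = pdb_file.get_structure()
        except Exception as exc:
            raise FormatError(f"cannot parse PDB file {topology!r}: {exc}") from exc
        return ConformationEnsemble(frames=np.asarray(stack.coord, dtype=float))

    import mdtraj

    suffix = "." + str(trajectory).rsplit(".", 1)[-1].lower()
    if suffix not in _BINARY_TRAJ:
        raise FormatError(
            f"unsupported trajectory format {suffix!r}; use XTC/TRR/DCD or a "
            "multi-model PDB"
        )
    top = mdtraj.load_topology(str(topology))
    n_ref = top.n_atoms
    try:
        traj = mdtraj.load(str(trajectory), top=top)
    except ValueError as exc:
        n_traj = _probe_trajectory_atoms(str(trajectory), suffix)
        raise FormatError(
            f"atom count mismatch: topology has {n_ref} atoms, trajectory "
            f"has {n_traj}"
        ) from exc
    if traj.n_atoms != n_ref:
        raise FormatError(
            f"atom count mismatch: topology has {n_ref} atoms, trajectory "
            f"has {traj.n_atoms}"
        )
    # mdtraj stores nm for every format; its xyz is already unit-normalised.
    frames = np.asarray(traj.xyz, dtype=float) * 10.0
    times = np.asarray(traj.time, dtype=float) / 1000.0  # ps -> ns
    return ConformationEnsemble(frames=frames, frame_times=times)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

def select_atoms(ref: ReferenceStructure, query: str) -> np.ndarray:
    """Resolve a selection query to sorted, duplicate-free 0-based indices.

    Grammar: clauses joined by ``and``; each clause is one of
    ``all`` | ``heavy`` | ``resid A-B`` or ``resid A,B,C`` |
    ``chain X`` | ``name N1,N2`` | ``element E1,E2``.
    """
    mask = np.ones(ref.n_atoms, dtype=bool)
    query = query.strip()
    if not query:
        raise SelectionError("empty selection query")
    for clause in re.split(r"\band\b", query):
        tokens = clause.strip().split()
        if not tokens:
            raise SelectionError(f"empty clause in query {query!r}")
        keyword = tokens[0].lower()
        if keyword == "all":
            continue
        elif keyword == "heavy":
            mask &= ref.heavy_mask
        elif keyword == "resid":
            if len(tokens) != 2:
                raise SelectionError(f"bad resid clause: {clause!r}")
            sel = np.zeros(ref.n_atoms, dtype=bool)
            for part in tokens[1].split(","):
                if "-" in part[1:]:  # allow negative ids
                    lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                    lo, hi = int(lo), int(hi)
                else:
                    lo = hi = int(part)
                present = (ref.residue_id >= lo) & (ref.residue_id <= hi)
                if not present.any():
                    raise SelectionError(f"no atoms with residue id in {part!r}")
                sel |= present
            mask &= sel
        elif keyword == "chain":
            if len(tokens) != 2:
                raise SelectionError(f"bad chain clause: {clause!r}")
            wanted = tokens[1].split(",")
            sel = np.isin(ref.chain_id, wanted)
            if not sel.any():
                raise SelectionError(f"no atoms in chain(s) {tokens[1]!r}")
            mask &= sel
        elif keyword == "name":
            if len(tokens) != 2:
                raise SelectionError(f"bad name clause: {clause!r}")
            mask &= np.isin(ref.atom_name, tokens[1].split(","))
        elif keyword == "element":
            if len(tokens) != 2:
                raise SelectionError(f"bad element clause: {clause!r}")
            mask &= np.isin(
                np.char.upper(ref.element.astype(str)),
                [e.upper() for e in tokens[1].split(",")],
            )
        else:
            raise SelectionError(f"unknown selection keyword {keyword!r}")
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"selection {query!r} matched no atoms")
    return indices


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _reference_to_atoms(ref: ReferenceStructure) -> struc.AtomArray:
    atoms = struc.AtomArray(ref.n_atoms)
    atoms.coord = ref.positions.astype(np.float32)
    atoms.atom_name = ref.atom_name
    atoms.element = ref.element
    atoms.res_id = ref.residue_id
    atoms.res_name = ref.residue_name
    atoms.chain_id = ref.chain_id
    atoms.hetero = np.zeros(ref.n_atoms, dtype=bool)
    return atoms


def write_ensemble_pdb(path, ref: ReferenceStructure, ensemble: ConformationEnsemble) -> None:
    """Write an ensemble as a multi-model PDB readable by :func:`load_ensemble`."""
    if ensemble.n_atoms != ref.n_atoms:
        raise ValueError(
            f"atom count mismatch: reference has {ref.n_atoms}, ensemble "
            f"has {ensemble.n_atoms}"
        )
    template = _reference_to_atoms(ref)
    stack = struc.from_template(template, ensemble.frames.astype(np.float32))
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


def write_bfactor_pdb(path, ref: ReferenceStructure, per_atom_values: np.ndarray) -> None:
    """Write the reference with per-atom values in the B-factor column.

    Used for hotspot maps on the 0 (blue) to 100 (red) scale.
    """
    values = np.asarray(per_atom_values, dtype=float)
    if values.shape != (ref.n_atoms,):
        raise ValueError("per_atom_values must have one entry per atom")
    atoms = _reference_to_atoms(ref)
    atoms.set_annotation("b_factor", values)
    out = pdb.PDBFile()
    out.set_structure(atoms)
    out.write(str(path))


def superpose_frames(
    ref: ReferenceStructure, ensemble: ConformationEnsemble
) -> ConformationEnsemble:
    """Least-squares (Kabsch) superposition of every frame onto the reference.

    For visual outputs only: chi is invariant under global rotations and
    translations, so no analysis requires this.
    """
    from scipy.spatial.transform import Rotation

    ref_centered = ref.positions - ref.positions.mean(axis=0)
    out = np.empty_like(ensemble.frames)
    for t, frame in enumerate(ensemble.frames):
        centroid = frame.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, frame - centroid)
        out[t] = (frame - centroid) @ rot.as_matrix().T + ref.positions.mean(axis=0)
    return ConformationEnsemble(frames=out, frame_times=ensemble.frame_times)


def write_mode_pdb(path, ref: ReferenceStructure, displacement: np.ndarray, scale: float = 1.0) -> None:
    """Write a 2-model PDB (reference; reference + scale * displacement).

    The displacement is a per-atom (N, 3) field, zero outside the atoms it
    covers; viewers can animate between the two models to visualise a mode.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape != ref.positions.shape:
        raise ValueError("displacement must be (N, 3) matching the reference")
    frames = np.stack([ref.positions, ref.positions + scale * displacement])
    write_ensemble_pdb(path, ref, ConformationEnsemble(frames=frames))
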