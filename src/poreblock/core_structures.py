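"""Structures, trajectories, C3 symmetry, and pore-axis alignment.

Conventions used throughout the package:

* coordinates are in angstroms, in a right-handed frame;
* the pore (symmetry) axis is +z, with the extracellular side at larger z;
* residue numbering is author/PDB numbering (1-based, cASIC1 scheme) — the
  rASIC3<->cASIC1 equivalence (e.g. Glu435 <-> Gly429) is a mapping the caller
  supplies, never arithmetic done here;
* when a periodic box is present, all distances use the minimum-image
  convention; without a box, plain Euclidean distances.

File I/O (PDB via biotite, DCD via mdtraj) converts to and from the plain
dataclass containers defined here; downstream modules only ever see these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from mdtraj.formats import DCDTrajectoryFile

__all__ = [
    "AtomRecord",
    "Structure",
    "Frame",
    "Trajectory",
    "ResidueRingSelection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "apply_c3_symmetry",
    "align_principal_axis",
    "select_ring",
    "minimum_image_displacement",
    "pair_distance",
]

WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "SPC"})


class StructureError(ValueError):
    """Raised for malformed structures, selections, or parse failures."""


@dataclass(eq=False)
class AtomRecord:
    """One atom: identity, residue context, and position in angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    partial_charge: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.serial}: position must be a finite 3-vector"
            )
        if self.radius is not None and self.radius < 0:
            raise StructureError(f"atom {self.serial}: negative radius")


@dataclass(eq=False)
class Structure:
    """An ordered collection of atoms with an optional periodic box (lengths, A)."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise StructureError("box must be 3 positive lengths")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def subunit_ids(self) -> list[str]:
        """Distinct chain labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, box=None if self.box is None else self.box.copy(),
                         meta=dict(self.meta))


@dataclass(eq=False)
class Frame:
    """Coordinates of one trajectory snapshot."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("frame coordinates must be N x 3")
        if self.time_index < 0:
            raise StructureError("time_index must be >= 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if np.any(self.box <= 0):
                raise StructureError("frame box lengths must be > 0")


@dataclass(eq=False)
class Trajectory:
    """A topology plus ordered frames recorded every ``frame_interval`` ps."""

    topology: Structure
    frames: list[Frame]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise StructureError("frame_interval must be > 0")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {f.time_index} has {f.coordinates.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def structure_at(self, i: int) -> Structure:
        """Topology with the coordinates (and box) of frame ``i``."""
        frame = self.frames[i]
        s = self.topology.with_coordinates(frame.coordinates)
        if frame.box is not None:
            s.box = frame.box.copy()
        return s


@dataclass(eq=False)
class ResidueRingSelection:
    """The three symmetry-related copies of one atom (e.g. the Asp433 Calphas)."""

    position: int
    atom_name: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if len(self.atoms) != 3:
            raise StructureError("a residue ring has exactly 3 atoms")

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


# ---------------------------------------------------------------------------
# periodic distances


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Displacement b - a, wrapped to the nearest periodic image when boxed."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return d


def pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    return float(np.linalg.norm(minimum_image_displacement(a, b, box)))


# ---------------------------------------------------------------------------
# PDB / DCD I/O (biotite and mdtraj behind the dataclass surface)


def _from_atom_array(arr: AtomArray, box: np.ndarray | None) -> Structure:
    n = arr.array_length()
    if n == 0:
        raise StructureError("empty model")
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    charges = None
    if "charge" in arr.get_annotation_categories():
        charges = arr.get_annotation("charge")
    atoms = []
    for i in range(n):
        atoms.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=np.array(arr.coord[i], dtype=float),
                partial_charge=None if charges is None else float(charges[i]) or None,
            )
        )
    return Structure(atoms=atoms, box=box)


def _to_atom_array(structure: Structure, charge_in_b_factor: bool = False) -> AtomArray:
    n = structure.n_atoms
    arr = AtomArray(n)
    arr.coord = structure.coordinates().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    hetero = np.array(
        [a.residue_name in WATER_RESIDUE_NAMES or a.element in ("CA", "NA", "CL")
         for a in structure.atoms]
    )
    arr.hetero = hetero
    if charge_in_b_factor:
        arr.set_annotation(
            "b_factor",
            np.array([a.partial_charge or 0.0 for a in structure.atoms]),
        )
    if structure.box is not None:
        arr.box = np.diag(structure.box).astype(np.float32)
    return arr


def _pdb_box(pdb: PDBFile) -> np.ndarray | None:
    try:
        arr = pdb.get_structure(model=1)
    except Exception:
        return None
    if arr.box is None:
        return None
    lengths = np.linalg.norm(np.asarray(arr.box, dtype=float), axis=-1)
    if np.any(lengths <= 0):
        return None
    return lengths


def read_structure(path: str | Path, model_index: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model_index`` follows the PDB MODEL numbering (1-based); files without
    MODEL records count as a single model 1.  Alternate locations are resolved
    to the highest-occupancy conformer (ties -> first encountered, biotite's
    ``altloc="occupancy"`` rule).  HETATM ions and waters are retained.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=model_index, altloc="occupancy", extra_fields=["atom_id"]
        )
    except StructureError:
        raise
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _from_atom_array(arr, _pdb_box(pdb))


def write_structure(
    structure: Structure, path: str | Path, charge_in_b_factor: bool = False
) -> None:
    """Write a PDB file.  ``charge_in_b_factor`` stores partial charges in the
    B-factor column (documented convention for dummy-ion models)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure, charge_in_b_factor))
    pdb.write(str(path))


def read_trajectory(topology: Structure, path: str | Path) -> Trajectory:
    """Read a DCD (CHARMM/NAMD dialect) or multi-model PDB as a trajectory."""
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    frames: list[Frame] = []
    if path.suffix.lower() == ".dcd":
        with DCDTrajectoryFile(str(path)) as fh:
            xyz, cell_lengths, _ = fh.read()
        for i in range(xyz.shape[0]):
            box = None
            if cell_lengths is not None and np.all(cell_lengths[i] > 0):
                box = np.asarray(cell_lengths[i], dtype=float)
            frames.append(Frame(coordinates=np.asarray(xyz[i], dtype=float),
                                box=box, time_index=i))
    else:
        pdb = PDBFile.read(str(path))
        box = _pdb_box(pdb)
        stack = pdb.get_structure(model=None, altloc="occupancy")
        coords = stack.coord if isinstance(stack, AtomArrayStack) else stack.coord[None]
        for i in range(coords.shape[0]):
            frames.append(Frame(coordinates=np.asarray(coords[i], dtype=float),
                                box=box, time_index=i))
    for f in frames:
        if f.coordinates.shape[0] != topology.n_atoms:
            raise StructureError(
                f"trajectory has {f.coordinates.shape[0]} atoms per frame, "
                f"topology has {topology.n_atoms}"
            )
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as DCD (``.dcd``) or multi-model PDB (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        n = traj.n_frames
        xyz = np.stack([f.coordinates for f in traj.frames]).astype(np.float32)
        boxed = all(f.box is not None for f in traj.frames)
        cl = ca = None
        if boxed:
            cl = np.stack([f.box for f in traj.frames]).astype(np.float32)
            ca = np.full((n, 3), 90.0, dtype=np.float32)
        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(xyz, cell_lengths=cl, cell_angles=ca)
    else:
        base = _to_atom_array(traj.topology)
        stack = AtomArrayStack(traj.n_frames, traj.topology.n_atoms)
        for cat in base.get_annotation_categories():
            stack.set_annotation(cat, base.get_annotation(cat))
        stack.coord = np.stack([f.coordinates for f in traj.frames]).astype(np.float32)
        if base.box is not None:
            stack.box = np.repeat(base.box[None], traj.n_frames, axis=0)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))


# ---------------------------------------------------------------------------
# symmetry and alignment


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise StructureError("symmetry axis must be non-zero")
    k = axis / norm
    t = math.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def apply_c3_symmetry(monomer: Structure, axis: np.ndarray = (0.0, 0.0, 1.0)) -> Structure:
    """Expand a monomer into an exact C3 trimer about ``axis`` through the origin.

    Subunits are the 0, 120 and 240 degree images, relabelled A/B/C in rotation
    order; the monomer's original chain label is kept in ``meta['source_chain']``.
    Serials are renumbered 1..3N to stay unique.
    """
    if monomer.n_atoms == 0:
        raise StructureError("monomer is empty")
    atoms: list[AtomRecord] = []
    serial = 1
    source = monomer.subunit_ids
    for label, angle in zip("ABC", (0.0, 120.0, 240.0)):
        rot = _rotation_about_axis(axis, angle)
        for a in monomer.atoms:
            atoms.append(
                replace(
                    a,
                    serial=serial,
                    chain_id=label,
                    position=rot @ a.position,
                )
            )
            serial += 1
    return Structure(
        atoms=atoms,
        box=None if monomer.box is None else monomer.box.copy(),
        meta={**monomer.meta, "source_chain": source},
    )


def _inertia_axis(coords: np.ndarray) -> np.ndarray:
    """Smallest-moment principal axis of unit-mass points (the bundle axis
    for a prolate helix bundle).  Raises on collinear/degenerate input."""
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 3:
        raise StructureError("need >= 3 atoms to define a principal axis")
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise StructureError("collinear atoms: principal axis undefined")
    r2 = np.sum(centered**2, axis=1)
    inertia = np.eye(3) * r2.sum() - centered.T @ centered
    evals, evecs = np.linalg.eigh(inertia)
    # the axis must be the *unique* smallest moment; a near-tie means the
    # structure has no preferred elongation direction
    if evals[1] - evals[0] < 1e-6 * max(evals[2], 1.0):
        raise StructureError("degenerate inertia spectrum: axis ill-defined")
    return evecs[:, 0]


def align_principal_axis(structure: Structure, atom_name: str = "CA") -> Structure:
    """Rigidly move the structure so its principal (pore) axis is +z and the
    centroid sits at the origin.

    The axis is the smallest-moment inertia eigenvector of the ``atom_name``
    atoms (all atoms if none match).  The eigenvector sign is chosen to make
    the rotation minimal, so an already-aligned structure is unchanged.
    """
    coords = structure.coordinates()
    sel = np.array([a.name == atom_name for a in structure.atoms])
    ref = coords[sel] if sel.sum() >= 3 else coords
    axis = _inertia_axis(ref)
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    new = (coords - ref.mean(axis=0)) @ rot.T
    new -= new[sel].mean(axis=0) if sel.sum() >= 3 else new.mean(axis=0)
    return structure.with_coordinates(new)


def select_ring(structure: Structure, position: int, atom_name: str = "CA") -> ResidueRingSelection:
    """Select the three symmetry-related copies of one atom, ordered by chain.

    Requires a trimeric structure, exactly one matching atom per subunit, and
    the same residue type in all three chains (an asymmetric ring — e.g. a
    mutation present in only one subunit — is an error).
    """
    non_protein = WATER_RESIDUE_NAMES | {"CAL", "SOD", "CLA", "POT", "MG", "DCA"}
    chains = [
        c
        for c in structure.subunit_ids
        if any(
            a.chain_id == c and a.residue_name not in non_protein
            for a in structure.atoms
        )
    ]
    if len(chains) != 3:
        raise StructureError(
            f"structure has {len(chains)} protein subunits, expected a trimer"
        )
    picked: list[AtomRecord] = []
    for chain in sorted(chains):
        matches = [
            a
            for a in structure.atoms
            if a.chain_id == chain
            and a.residue_number == position
            and a.name == atom_name
        ]
        if not matches:
            raise StructureError(
                f"no atom {atom_name} at position {position} in chain {chain}"
            )
        if len(matches) > 1:
            raise StructureError(
                f"ambiguous ring: {len(matches)} atoms {atom_name}/{position} "
                f"in chain {chain}"
            )
        picked.append(matches[0])
    resnames = {a.residue_name for a in picked}
    if len(resnames) != 1:
        raise StructureError(
            f"asymmetric ring at position {position}: residue types {sorted(resnames)}"
        )
    return ResidueRingSelection(position=position, atom_name=atom_name, atoms=picked)
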