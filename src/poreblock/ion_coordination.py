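"""Ca2+ coordination-shell detection, geometry classification, and the
multisite (dummy-atom) cation model.

A bound Ca2+ is characterised by its first coordination shell: ligand atoms
(carboxylate oxygens, backbone carbonyl oxygens, water oxygens, thiolate
sulfurs) within per-chemistry distance cutoffs.  A carboxylate donating both
oxygens (bidentate) contributes two ligands to the coordination number, the
usual situation when CN exceeds 6.  The shell's shape is classified against
ideal templates — octahedron (CN 6) and pentagonal bipyramid (CN 7) — by
finding the vertex assignment and rigid rotation that minimise the angular
RMSD between observed ligand directions and template directions.

Default cutoffs: Ca-O 3.0 A, Ca-S 3.2 A (first-shell Ca2+-oxygen distances
cluster near 2.4 A).  A shell is labelled ``other`` when no template matches
its CN or the best angular RMSD exceeds 15 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_structures import (
    AtomRecord,
    Structure,
    Trajectory,
    minimum_image_displacement,
    WATER_RESIDUE_NAMES,
)

__all__ = [
    "Ligand",
    "CoordinationShell",
    "GeometryClassification",
    "CoordinationStats",
    "DummyIonModel",
    "DEFAULT_CUTOFFS",
    "find_ligands",
    "coordination_shell",
    "classify_geometry",
    "coordination_statistics",
    "build_dummy_ion",
    "ideal_template",
]

DEFAULT_CUTOFFS: dict[str, float] = {
    "carboxylate_O": 3.0,
    "backbone_O": 3.0,
    "water_O": 3.0,
    "thiolate_S": 3.2,
}

ANGULAR_RMSD_THRESHOLD = 15.0  # degrees

_CARBOXYLATE_OXYGENS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass(eq=False)
class Ligand:
    atom: AtomRecord
    chemistry: str
    distance: float
    denticity_partner: AtomRecord | None = None


@dataclass(eq=False)
class CoordinationShell:
    ion: AtomRecord
    ligands: list[Ligand]

    @property
    def CN(self) -> int:
        return len(self.ligands)

    @property
    def n_waters(self) -> int:
        return sum(1 for l in self.ligands if l.chemistry == "water_O")

    @property
    def n_bidentate(self) -> int:
        """Number of bidentate carboxylate groups (pairs, not oxygens)."""
        return sum(1 for l in self.ligands if l.denticity_partner is not None) // 2


@dataclass(eq=False)
class GeometryClassification:
    label: str  # octahedral | pentagonal_bipyramidal | other
    angular_rmsd: float  # degrees
    template_assignment: tuple[int, ...] | None = None


def _chemistry_of(atom: AtomRecord) -> str:
    if atom.residue_name in WATER_RESIDUE_NAMES:
        return "water_O" if atom.element == "O" or atom.name.startswith("O") else "other"
    if atom.name in _CARBOXYLATE_OXYGENS.get(atom.residue_name, ()):
        return "carboxylate_O"
    if atom.name == "SG" and atom.residue_name == "CYS":
        return "thiolate_S"
    if atom.name == "O":
        return "backbone_O"
    if atom.element == "O":
        warnings.warn(
            f"no chemistry template for {atom.residue_name}/{atom.name}; "
            "treating as 'other'"
        )
        return "other"
    return "other"


def find_ligands(
    structure: Structure,
    ion: AtomRecord,
    cutoffs: dict[str, float] | None = None,
) -> list[Ligand]:
    """All atoms of recognised ligand chemistries within their cutoff of the
    ion, sorted by distance; bidentate carboxylate oxygen pairs (same residue,
    both in the shell) are mutually flagged via ``denticity_partner``."""
    cutoffs = dict(DEFAULT_CUTOFFS, **(cutoffs or {}))
    max_cut = max(cutoffs.values())
    ligands: list[Ligand] = []
    for atom in structure.atoms:
        if atom is ion:
            continue
        chem = _chemistry_of(atom)
        if chem not in cutoffs:
            continue
        d = float(
            np.linalg.norm(
                minimum_image_displacement(ion.position, atom.position, structure.box)
            )
        )
        if d <= min(cutoffs[chem], max_cut) and d <= cutoffs[chem]:
            ligands.append(Ligand(atom=atom, chemistry=chem, distance=d))
    ligands.sort(key=lambda l: (l.distance, l.atom.serial))
    # bidentate flagging: both oxygens of one carboxylate group in the shell
    by_residue: dict[tuple, list[Ligand]] = {}
    for l in ligands:
        if l.chemistry == "carboxylate_O":
            key = (l.atom.chain_id, l.atom.residue_number, l.atom.residue_name)
            by_residue.setdefault(key, []).append(l)
    for group in by_residue.values():
        if len(group) == 2:
            group[0].denticity_partner = group[1].atom
            group[1].denticity_partner = group[0].atom
    return ligands


def coordination_shell(
    structure: Structure,
    ion: AtomRecord,
    cutoffs: dict[str, float] | None = None,
) -> CoordinationShell:
    return CoordinationShell(ion=ion, ligands=find_ligands(structure, ion, cutoffs))


# ---------------------------------------------------------------------------
# geometry classification


def ideal_template(label: str) -> np.ndarray:
    """Unit vertex directions of an ideal coordination polyhedron."""
    if label == "octahedral":
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    if label == "pentagonal_bipyramidal":
        eq = [
            [math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0]
            for k in range(5)
        ]
        return np.array(eq + [[0, 0, 1], [0, 0, -1]], dtype=float)
    raise ValueError(f"no template named {label!r}")


_TEMPLATES_BY_CN = {6: ("octahedral",), 7: ("pentagonal_bipyramidal",)}


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation R minimising ||P - Q R^T||, i.e. mapping Q onto P."""
    H = Q.T @ P
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _angular_rmsd(obs: np.ndarray, tmpl_rotated: np.ndarray) -> float:
    cosines = np.clip(np.sum(obs * tmpl_rotated, axis=1), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosines))
    return float(np.sqrt(np.mean(angles**2)))


def _fit_assignment(
    obs: np.ndarray, tmpl: np.ndarray, rot0: np.ndarray, max_iter: int = 20
) -> tuple[float, tuple[int, ...]]:
    """Alternate Hungarian assignment (on the angular cost matrix) and Kabsch
    rotation refits until the assignment stabilises."""
    rot = rot0
    prev: tuple[int, ...] | None = None
    perm: tuple[int, ...] = tuple(range(len(obs)))
    for _ in range(max_iter):
        rotated = tmpl @ rot.T
        cos = np.clip(obs @ rotated.T, -1.0, 1.0)
        cost = np.degrees(np.arccos(cos)) ** 2
        rows, cols = linear_sum_assignment(cost)
        perm = tuple(int(c) for c in cols[np.argsort(rows)])
        if perm == prev:
            break
        prev = perm
        rot = _kabsch(obs, tmpl[list(perm)])
    rot = _kabsch(obs, tmpl[list(perm)])
    return _angular_rmsd(obs, tmpl[list(perm)] @ rot.T), perm


def _seed_rotations(obs: np.ndarray, tmpl: np.ndarray) -> list[np.ndarray]:
    """Deterministic starting rotations: map template vertex 0 onto each
    observed direction, with several rolls about that direction."""
    seeds = [np.eye(3)]
    t0 = tmpl[0]
    for u in obs:
        v = np.cross(t0, u)
        s = np.linalg.norm(v)
        c = float(t0 @ u)
        if s < 1e-12:
            base = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            base = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        for roll in (0.0, 72.0, 144.0, 216.0, 288.0):
            t = math.radians(roll)
            k = u
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
            seeds.append(R @ base)
    return seeds


def classify_geometry(shell: CoordinationShell) -> GeometryClassification:
    """Best-matching ideal polyhedron for the shell's ligand directions.

    For CN 6 and 7 the octahedron and pentagonal bipyramid are tried; the
    vertex assignment and rigid rotation minimising the angular RMSD are
    found by iterated optimal assignment with Kabsch refits from multiple
    deterministic starts.  RMSD above 15 degrees (or an unsupported CN)
    yields ``other``; an exact tie between templates also yields ``other``.
    """
    cn = shell.CN
    labels = _TEMPLATES_BY_CN.get(cn, ())
    if not labels:
        return GeometryClassification(label="other", angular_rmsd=math.inf)
    vecs = np.array(
        [
            minimum_image_displacement(shell.ion.position, l.atom.position, None)
            for l in shell.ligands
        ]
    )
    norms = np.linalg.norm(vecs, axis=1)
    obs = vecs / norms[:, None]
    best: list[tuple[float, str, tuple[int, ...]]] = []
    for label in labels:
        tmpl = ideal_template(label)
        rmsd_best, perm_best = math.inf, None
        for rot0 in _seed_rotations(obs, tmpl):
            rmsd, perm = _fit_assignment(obs, tmpl, rot0)
            if rmsd < rmsd_best:
                rmsd_best, perm_best = rmsd, perm
        best.append((rmsd_best, label, perm_best))
    best.sort(key=lambda x: x[0])
    rmsd, label, perm = best[0]
    if rmsd > ANGULAR_RMSD_THRESHOLD:
        return GeometryClassification(label="other", angular_rmsd=rmsd)
    if len(best) > 1 and best[1][0] == rmsd:
        return GeometryClassification(label="other", angular_rmsd=rmsd)
    return GeometryClassification(label=label, angular_rmsd=rmsd, template_assignment=perm)


# ---------------------------------------------------------------------------
# trajectory aggregation


@dataclass(eq=False)
class CoordinationStats:
    cn_trace: np.ndarray
    geometry_occupancy: dict[str, float]
    bond_length_stats: dict[str, tuple[float, float]]  # chemistry -> (mean, sd)
    cis_angle_stats: tuple[float, float]  # (mean, sd) of <120 deg L-ion-L angles


def _select_ion(structure: Structure, ion_selector) -> AtomRecord | None:
    if callable(ion_selector):
        matches = [a for a in structure.atoms if ion_selector(a)]
    else:
        matches = [a for a in structure.atoms if a.residue_name == ion_selector]
    return matches[0] if matches else None


def coordination_statistics(
    traj: Trajectory,
    ion_selector="CAL",
    cutoffs: dict[str, float] | None = None,
    window: float = 1.0,
) -> CoordinationStats:
    """Aggregate per-frame shells over the last ``window`` fraction of frames.

    ``ion_selector`` is a residue name or a predicate over atoms.  Frames
    where the ion is absent are recorded as CN = 0 with a warning.  The cis
    angle statistic pools all ligand-ion-ligand angles below 120 degrees.
    """
    start = int(round(traj.n_frames * (1.0 - window)))
    cns: list[int] = []
    label_counts: dict[str, int] = {}
    lengths: dict[str, list[float]] = {}
    cis_angles: list[float] = []
    for i in range(start, traj.n_frames):
        s = traj.structure_at(i)
        ion = _select_ion(s, ion_selector)
        if ion is None:
            warnings.warn(f"ion absent in frame {i}; recording CN = 0")
            cns.append(0)
            label_counts["other"] = label_counts.get("other", 0) + 1
            continue
        shell = coordination_shell(s, ion, cutoffs)
        cns.append(shell.CN)
        geo = classify_geometry(shell)
        label_counts[geo.label] = label_counts.get(geo.label, 0) + 1
        for l in shell.ligands:
            lengths.setdefault(l.chemistry, []).append(l.distance)
        vecs = np.array([l.atom.position - ion.position for l in shell.ligands])
        if len(vecs) >= 2:
            unit = vecs / np.linalg.norm(vecs, axis=1)[:, None]
            for a in range(len(unit)):
                for b in range(a + 1, len(unit)):
                    ang = math.degrees(
                        math.acos(float(np.clip(unit[a] @ unit[b], -1, 1)))
                    )
                    if ang < 120.0:
                        cis_angles.append(ang)
    n = len(cns)
    occupancy = {k: v / n for k, v in label_counts.items()}
    length_stats = {
        chem: (float(np.mean(v)), float(np.std(v))) for chem, v in lengths.items()
    }
    cis = (
        (float(np.mean(cis_angles)), float(np.std(cis_angles)))
        if cis_angles
        else (math.nan, math.nan)
    )
    return CoordinationStats(
        cn_trace=np.array(cns),
        geometry_occupancy=occupancy,
        bond_length_stats=length_stats,
        cis_angle_stats=cis,
    )


# ---------------------------------------------------------------------------
# multisite (dummy-atom) cation model


@dataclass(eq=False)
class DummyIonModel:
    """A divalent cation as a central atom plus charged satellite sites at
    ideal octahedral directions; total charge is exactly +2 e."""

    central_charge: float
    n_sites: int
    site_charge: float
    site_distance: float
    site_geometry: str = "octahedral"

    @property
    def total_charge(self) -> float:
        return self.central_charge + self.n_sites * self.site_charge

    def to_structure(self) -> Structure:
        """Central atom + satellites as a Structure (charges on the atoms;
        written to the B-factor column by the PDB writer convention)."""
        atoms = [
            AtomRecord(1, "CA", "CA", "DCA", 1, "X", np.zeros(3),
                       partial_charge=self.central_charge)
        ]
        tmpl = ideal_template("octahedral")[: self.n_sites]
        for i, u in enumerate(tmpl):
            atoms.append(
                AtomRecord(2 + i, f"D{i + 1}", "D", "DCA", 1, "X",
                           u * self.site_distance, partial_charge=self.site_charge)
            )
        return Structure(atoms=atoms)


def build_dummy_ion(
    n_sites: int = 6, site_distance: float = 0.9, site_charge: float = 0.3
) -> DummyIonModel:
    """Multisite Ca2+ model: the central charge is set so the total is +2 e."""
    if n_sites < 2 or n_sites > 6:
        raise ValueError("n_sites must be in [2, 6] for the octahedral template")
    if site_distance <= 0:
        raise ValueError("site_distance must be positive")
    central = 2.0 - n_sites * site_charge
    model = DummyIonModel(
        central_charge=central,
        n_sites=n_sites,
        site_charge=site_charge,
        site_distance=site_distance,
    )
    if abs(model.total_charge - 2.0) > 1e-12:
        raise ValueError("total charge is not representable as exactly +2")
    return model
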