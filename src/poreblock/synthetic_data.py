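"""Synthetic fixture generators for every downstream analysis stage.

Microsecond membrane-protein trajectories cannot be regenerated at desk
scale, so each analysis is exercised on small synthetic systems that carry
exactly the geometric and statistical structure the analyses assume:

* ideal (optionally noise-jittered) Ca2+ coordination shells — octahedral or
  pentagonal-bipyramidal — built from a declarative ligand roster;
* a C3-symmetric pseudo-pore scaffold with marker Calpha rings at the three
  pore-lining positions (429 / 433 / 436 in cASIC1 numbering);
* trajectories over that scaffold with prescribed per-ring triangle-area
  statistics, axial water placement, optional gate-spanning water chains,
  monovalent ions above the gate, and an optional bound divalent cation;
* Hill-model pH dose-response data with per-cell Gaussian noise.

Every generator is deterministic under a fixed seed (bitwise-reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_structures import AtomRecord, Frame, Structure, Trajectory

__all__ = [
    "LigandSpec",
    "CoordinationFixtureSpec",
    "TrajectorySpec",
    "DoseResponseSpec",
    "SystemSpec",
    "build_coordination_fixture",
    "build_channel_scaffold",
    "simulate_trajectory",
    "simulate_dose_response",
    "hill_response",
    "box_ion_concentration",
    "MUTANT_SITE_ROSTER",
    "WILD_TYPE_SITE_ROSTER",
]

AVOGADRO = 6.02214076e23

# chemistry -> (residue name, donor atom name, element)
_CHEMISTRY_ATOMS = {
    "carboxylate_O": None,  # depends on residue (ASP: OD1/OD2, GLU: OE1/OE2)
    "backbone_O": ("O", "O"),
    "water_O": ("O", "O"),
    "thiolate_S": ("SG", "S"),
}

_CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CARBOXYLATE_C = {"ASP": "CG", "GLU": "CD"}


@dataclass(frozen=True)
class LigandSpec:
    """One roster entry: where a coordinating atom comes from."""

    chemistry: str  # carboxylate_O | backbone_O | water_O | thiolate_S
    residue_name: str
    residue_number: int
    subunit: str
    denticity: str = "mono"  # mono | bi (bi only for carboxylate_O)

    def n_vertices(self) -> int:
        return 2 if self.denticity == "bi" else 1


@dataclass
class CoordinationFixtureSpec:
    geometry: str  # octahedral | pentagonal_bipyramidal
    ligand_roster: list[LigandSpec]
    bond_length: float = 2.4
    angular_noise_sd: float = 0.0  # degrees
    seed: int = 0


# The two binding-site rosters observed in the simulations: the mutant
# (G429E) site with all three gate aspartates (one bidentate), the introduced
# glutamate, and two waters (7 vertices, pentagonal bipyramid); the wild-type
# site with one aspartate oxygen per subunit plus three waters (octahedron).
MUTANT_SITE_ROSTER = [
    LigandSpec("carboxylate_O", "ASP", 433, "A", "bi"),
    LigandSpec("carboxylate_O", "ASP", 433, "B"),
    LigandSpec("carboxylate_O", "ASP", 433, "C"),
    LigandSpec("carboxylate_O", "GLU", 429, "A"),
    LigandSpec("water_O", "HOH", 1001, "W"),
    LigandSpec("water_O", "HOH", 1002, "W"),
]

WILD_TYPE_SITE_ROSTER = [
    LigandSpec("carboxylate_O", "ASP", 433, "A"),
    LigandSpec("carboxylate_O", "ASP", 433, "B"),
    LigandSpec("carboxylate_O", "ASP", 433, "C"),
    LigandSpec("water_O", "HOH", 1001, "W"),
    LigandSpec("water_O", "HOH", 1002, "W"),
    LigandSpec("water_O", "HOH", 1003, "W"),
]


def _ideal_vertices(geometry: str) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unit vertex directions and the adjacent-vertex pairs a bidentate
    carboxylate may occupy."""
    if geometry == "octahedral":
        verts = np.array(
            [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        pairs = [(0, 1), (2, 3)]  # 90 degree neighbours
    elif geometry == "pentagonal_bipyramidal":
        eq = [
            [math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0]
            for k in range(5)
        ]
        verts = np.array(eq + [[0, 0, 1], [0, 0, -1]], dtype=float)
        pairs = [(0, 1), (2, 3)]  # 72 degree equatorial neighbours
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return verts, pairs


def _jitter_direction(u: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate a unit vector by an angle ~ N(0, sd) about a random axis
    perpendicular to it."""
    if sd_deg == 0.0:
        return u
    # deterministic draw order: axis angle first, magnitude second
    phi = rng.uniform(0.0, 2 * math.pi)
    theta = math.radians(rng.normal(0.0, sd_deg))
    # orthonormal frame around u
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    axis = math.cos(phi) * e1 + math.sin(phi) * e2
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
    return rot @ u


def build_coordination_fixture(spec: CoordinationFixtureSpec) -> Structure:
    """Place an ion at the origin with roster ligands at ideal polyhedron
    vertices (bidentate carboxylates take two adjacent vertices and carry
    their carboxylate carbon 2.2 A behind the O-O midpoint)."""
    verts, bi_pairs = _ideal_vertices(spec.geometry)
    n_needed = sum(l.n_vertices() for l in spec.ligand_roster)
    if n_needed != len(verts):
        raise ValueError(
            f"roster occupies {n_needed} vertices but {spec.geometry} has "
            f"{len(verts)}"
        )
    rng = np.random.default_rng(spec.seed)

    available = list(range(len(verts)))
    pair_queue = [p for p in bi_pairs]
    atoms: list[AtomRecord] = [
        AtomRecord(1, "CA", "CA", "CAL", 1, "X", np.zeros(3))
    ]
    serial = 2

    def place(direction: np.ndarray, name: str, element: str, lig: LigandSpec) -> None:
        nonlocal serial
        u = _jitter_direction(direction, spec.angular_noise_sd, rng)
        atoms.append(
            AtomRecord(
                serial, name, element, lig.residue_name, lig.residue_number,
                lig.subunit, u * spec.bond_length,
            )
        )
        serial += 1

    # bidentate entries first (they need intact adjacent pairs), then monos
    bi_ligands = [l for l in spec.ligand_roster if l.denticity == "bi"]
    mono_ligands = [l for l in spec.ligand_roster if l.denticity != "bi"]
    for lig in bi_ligands:
        if lig.chemistry != "carboxylate_O":
            raise ValueError("bidentate is only defined for carboxylate_O")
        if not pair_queue:
            raise ValueError("no adjacent vertex pair left for bidentate ligand")
        i, j = pair_queue.pop(0)
        available.remove(i)
        available.remove(j)
        o_names = _CARBOXYLATE_O[lig.residue_name]
        place(verts[i], o_names[0], "O", lig)
        place(verts[j], o_names[1], "O", lig)
        mid = 0.5 * (atoms[-2].position + atoms[-1].position)
        out = mid / np.linalg.norm(mid)
        atoms.append(
            AtomRecord(
                serial, _CARBOXYLATE_C[lig.residue_name], "C",
                lig.residue_name, lig.residue_number, lig.subunit,
                mid + 2.2 * out,
            )
        )
        serial += 1
    for lig in mono_ligands:
        idx = available.pop(0)
        if lig.chemistry == "carboxylate_O":
            name = _CARBOXYLATE_O[lig.residue_name][0]
            element = "O"
        else:
            name, element = _CHEMISTRY_ATOMS[lig.chemistry]
        place(verts[idx], name, element, lig)
        if lig.chemistry == "carboxylate_O":
            out = verts[idx]
            atoms.append(
                AtomRecord(
                    serial, _CARBOXYLATE_C[lig.residue_name], "C",
                    lig.residue_name, lig.residue_number, lig.subunit,
                    (spec.bond_length + 1.25) * out,
                )
            )
            serial += 1
    return Structure(atoms=atoms, meta={"geometry": spec.geometry})


# ---------------------------------------------------------------------------
# pseudo-pore scaffold and trajectories

HELIX_RISE = 1.5  # A per residue along the pore axis
MARKER_POSITIONS = (429, 433, 436)


def build_channel_scaffold(
    radius_by_position: dict[int, float],
    helix_length: float = 30.0,
    residue_429: str = "GLY",
) -> Structure:
    """A C3 trimer of Calpha rods along +z with marker rings at 429/433/436.

    Each subunit is a straight run of Calpha atoms (one per residue,
    ``HELIX_RISE`` A apart in z, position 433 at z = 0); the marker residues
    sit at the requested radial distances, the rest at their mean.  The gate
    region (z of the 433 ring +/- 2 A) is recorded in ``meta['gate_z_range']``.
    """
    for pos in MARKER_POSITIONS:
        if pos not in radius_by_position:
            raise ValueError(f"radius_by_position is missing marker position {pos}")
    if any(r <= 0 for r in radius_by_position.values()):
        raise ValueError("radii must be positive")
    default_r = float(np.mean(list(radius_by_position.values())))
    half = max(1, int(round(helix_length / 2.0 / HELIX_RISE)))
    res_names = {429: residue_429, 433: "ASP", 436: "GLY"}
    atoms = []
    serial = 1
    for resnum in range(433 - half, 433 + half + 1):
        r = radius_by_position.get(resnum, default_r)
        z = (resnum - 433) * HELIX_RISE
        atoms.append(
            AtomRecord(
                serial, "CA", "C", res_names.get(resnum, "ALA"), resnum, "A",
                np.array([r, 0.0, z]),
            )
        )
        serial += 1
    from .core_structures import apply_c3_symmetry

    trimer = apply_c3_symmetry(Structure(atoms=atoms))
    trimer.meta["gate_z_range"] = (-2.0, 2.0)
    trimer.meta["marker_positions"] = MARKER_POSITIONS
    trimer.meta["radius_by_position"] = dict(radius_by_position)
    return trimer


@dataclass
class TrajectorySpec:
    """Declarative description of a synthetic trajectory.

    ``area_series`` maps marker position -> (target mean triangle area in A^2,
    Gaussian sd); ``water_axial_density`` is a piecewise-constant axial
    profile as (z_lo, z_hi, count) slabs; waters in ``wire_frames`` are
    rearranged into a gate-spanning chain with 3.4 A O-O spacing (just under
    the 3.5 A detection cutoff, so detection is unambiguous).
    """

    n_frames: int
    area_series: dict[int, tuple[float, float]]
    ion_present: bool = False
    wire_frames: frozenset[int] = frozenset()
    water_axial_density: list[tuple[float, float, int]] = field(
        default_factory=lambda: [(4.0, 20.0, 40), (-20.0, -4.0, 40)]
    )
    n_sodium: int = 0
    pore_radius: float = 10.0
    wire_spacing: float = 3.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if any(a <= 0 for a, _ in self.area_series.values()):
            raise ValueError("target areas must be positive")
        bad = [i for i in self.wire_frames if not (0 <= i < self.n_frames)]
        if bad:
            raise ValueError(f"wire_frames outside [0, n_frames): {bad}")
        if any(c < 0 for _, _, c in self.water_axial_density):
            raise ValueError("negative water count in axial density")


def _radius_for_area(area: float) -> float:
    # equilateral ring of circumradius r: side r*sqrt(3), area (3*sqrt(3)/4) r^2
    return math.sqrt(area * 4.0 / (3.0 * math.sqrt(3.0)))


def simulate_trajectory(scaffold: Structure, spec: TrajectorySpec) -> Trajectory:
    """Generate a trajectory over the scaffold realising the requested
    per-ring area statistics, water placement, wire frames and ions."""
    gate = scaffold.meta.get("gate_z_range")
    if gate is None:
        raise ValueError("scaffold has no gate_z_range metadata (not a scaffold?)")
    gz0, gz1 = gate
    rng = np.random.default_rng(spec.seed)

    n_water = sum(c for _, _, c in spec.water_axial_density)
    wire_z = np.arange(gz0 - 2.0, gz1 + 2.0 + spec.wire_spacing, spec.wire_spacing)
    if spec.wire_frames and n_water < len(wire_z):
        raise ValueError(
            f"need at least {len(wire_z)} waters for a gate-spanning chain, "
            f"have {n_water}"
        )

    # indices of marker Calpha atoms per position, and their angular phase
    marker_idx: dict[int, list[int]] = {p: [] for p in spec.area_series}
    for i, a in enumerate(scaffold.atoms):
        if a.residue_number in marker_idx and a.name == "CA":
            marker_idx[a.residue_number].append(i)

    base = scaffold.coordinates()
    frames: list[Frame] = []
    for t in range(spec.n_frames):
        coords = base.copy()
        for pos, (mean_area, sd) in spec.area_series.items():
            area = mean_area if sd == 0 else max(rng.normal(mean_area, sd), 1e-6)
            r = _radius_for_area(area)
            for i in marker_idx[pos]:
                xy = base[i, :2]
                phase = xy / np.linalg.norm(xy)
                coords[i, :2] = r * phase

        water_xyz = np.empty((n_water, 3))
        k = 0
        for z_lo, z_hi, count in spec.water_axial_density:
            for _ in range(count):
                rad = spec.pore_radius * math.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2 * math.pi)
                water_xyz[k] = (rad * math.cos(ang), rad * math.sin(ang),
                                rng.uniform(z_lo, z_hi))
                k += 1
        if t in spec.wire_frames:
            water_xyz[: len(wire_z), 0] = 0.0
            water_xyz[: len(wire_z), 1] = 0.0
            water_xyz[: len(wire_z), 2] = wire_z

        extra = [water_xyz]
        if spec.ion_present:
            extra.append(np.array([[0.0, 0.0, gz1 + 1.0]]))
        if spec.n_sodium:
            na = np.empty((spec.n_sodium, 3))
            for j in range(spec.n_sodium):
                rad = 8.0 * math.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2 * math.pi)
                na[j] = (rad * math.cos(ang), rad * math.sin(ang),
                         rng.uniform(gz1 + 3.0, gz1 + 13.0))
            extra.append(na)
        frames.append(
            Frame(coordinates=np.vstack([coords] + extra), time_index=t)
        )

    atoms = [a for a in scaffold.atoms]
    serial = max(a.serial for a in atoms) + 1
    for w in range(n_water):
        atoms.append(AtomRecord(serial, "O", "O", "HOH", 1001 + w, "W", np.zeros(3)))
        serial += 1
    if spec.ion_present:
        atoms.append(AtomRecord(serial, "CA", "CA", "CAL", 2001, "X", np.zeros(3)))
        serial += 1
    for j in range(spec.n_sodium):
        atoms.append(AtomRecord(serial, "NA", "NA", "SOD", 3001 + j, "I", np.zeros(3)))
        serial += 1
    topology = Structure(atoms=atoms, meta=dict(scaffold.meta))
    topology = topology.with_coordinates(frames[0].coordinates)
    topology.meta = dict(scaffold.meta)
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# dose-response data


@dataclass
class DoseResponseSpec:
    """Hill-model pH activation data with per-cell Gaussian noise.

    The activation curve is f(pH) = 1 / (1 + 10^(nH * (pH - pH50))): currents
    grow as the solution acidifies, with half-maximal current at pH50.
    ``noise_sd`` is a fraction of Imax.
    """

    pH50: float
    nH: float
    Imax: float = 1000.0
    pH_grid: tuple[float, ...] = (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.2, 7.4, 7.6)
    noise_sd: float = 0.0
    n_cells: int = 1
    calcium_mM: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nH <= 0:
            raise ValueError("nH must be positive")
        if any(b <= a for a, b in zip(self.pH_grid, self.pH_grid[1:])):
            raise ValueError("pH_grid must be strictly increasing")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def hill_response(pH: np.ndarray, pH50: float, nH: float, Imax: float = 1.0) -> np.ndarray:
    """Proton-activation Hill curve I(pH) = Imax / (1 + 10^(nH (pH - pH50)))."""
    return Imax / (1.0 + 10.0 ** (nH * (np.asarray(pH, dtype=float) - pH50)))


def simulate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Per-cell dose-response records: cell_id, pH, current_pA, calcium_mM."""
    rng = np.random.default_rng(spec.seed)
    ph = np.asarray(spec.pH_grid, dtype=float)
    rows = []
    for cell in range(spec.n_cells):
        current = hill_response(ph, spec.pH50, spec.nH, spec.Imax)
        if spec.noise_sd > 0:
            current = current + rng.normal(0.0, spec.noise_sd * spec.Imax, ph.size)
        for p, i in zip(ph, current):
            rows.append((cell, p, i, spec.calcium_mM))
    return pd.DataFrame(rows, columns=["cell_id", "pH", "current_pA", "calcium_mM"])


# ---------------------------------------------------------------------------
# system sizing


@dataclass
class SystemSpec:
    """Simulation-box composition used for concentration checks."""

    box: tuple[float, float, float]  # A
    n_divalent: int = 1
    n_monovalent_pairs: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.box):
            raise ValueError("box lengths must be positive")


def box_ion_concentration(spec: SystemSpec) -> float:
    """Concentration of the divalent species in mM: n / (N_A * V)."""
    volume_l = float(np.prod(spec.box)) * 1e-27  # A^3 -> litres
    if volume_l <= 0:
        raise ValueError("box volume must be positive")
    return spec.n_divalent / (AVOGADRO * volume_l) * 1000.0
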