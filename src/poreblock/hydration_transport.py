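"""Pore hydration and transport observables.

* an axial (1-D) water density profile, Gaussian-smoothed per atom with a
  width of vdW radius x ``radius_scale`` (scale 2 reproduces the heavier
  smoothing used for trajectory density maps); each water contributes unit
  integral over the grid, so the profile integral always equals the mean
  water count regardless of the smoothing radius;
* detection of a continuous water wire: a chain of water oxygens at
  hydrogen-bond distance (O-O <= 3.5 A by default) connecting the region
  below the gate to the region above it, evaluated as graph connectivity;
* selection of the k waters closest to an ion (whole residues), the
  frame-preparation rule for end-point binding-energy estimates;
* gate-crossing counting for an ion's z-trace with hysteresis, so thermal
  jitter around the gate plane is not double-counted.

The gate region defaults to the z-interval of the Asp433 ring +/- 2 A,
carried in scaffold metadata as ``gate_z_range``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_structures import (
    AtomRecord,
    Structure,
    Trajectory,
    WATER_RESIDUE_NAMES,
)

__all__ = [
    "DensityProfile",
    "WireStats",
    "CrossingEvents",
    "water_density_profile",
    "detect_water_wire",
    "wire_probability",
    "k_closest_waters",
    "count_gate_crossings",
    "water_oxygen_indices",
]

OO_CUTOFF_DEFAULT = 3.5  # A, hydrogen-bond heavy-atom convention
VDW_RADIUS_O = 1.52  # A


def water_oxygen_indices(structure: Structure) -> np.ndarray:
    return np.array(
        [
            i
            for i, a in enumerate(structure.atoms)
            if a.residue_name in WATER_RESIDUE_NAMES
            and (a.element == "O" or a.name.startswith("O"))
        ],
        dtype=int,
    )


@dataclass(eq=False)
class DensityProfile:
    bin_centers: np.ndarray  # A along z
    density: np.ndarray  # waters / A
    smoothing_radius_scale: float

    def integral(self) -> float:
        dz = self.bin_centers[1] - self.bin_centers[0]
        return float(self.density.sum() * dz)


@dataclass(eq=False)
class WireStats:
    per_frame: np.ndarray  # boolean
    gate_z_range: tuple[float, float]

    @property
    def probability(self) -> float:
        """Percent of frames with a gate-spanning water wire."""
        if len(self.per_frame) == 0:
            return 0.0
        return 100.0 * float(np.count_nonzero(self.per_frame)) / len(self.per_frame)


@dataclass(eq=False)
class CrossingEvents:
    ion_serial: int
    crossing_frames: list[int]

    @property
    def count(self) -> int:
        return len(self.crossing_frames)


def water_density_profile(
    traj: Trajectory,
    z_range: tuple[float, float],
    grid_spacing: float = 0.5,
    radius_scale: float = 2.0,
) -> DensityProfile:
    """Mean axial water-oxygen density over all frames on a regular z grid.

    Each oxygen contributes a 1-D Gaussian of width sigma = vdW(O) x
    ``radius_scale`` normalised to unit mass *on the grid*, so the integral
    equals the mean number of waters whose Gaussians fall in the window and
    is invariant to the smoothing radius.
    """
    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise ValueError("empty z range")
    widx = water_oxygen_indices(traj.topology)
    edges = np.arange(z_lo, z_hi + grid_spacing, grid_spacing)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = np.zeros_like(centers)
    if widx.size == 0 or traj.n_frames == 0:
        warnings.warn("no waters in the region; returning a zero profile")
        return DensityProfile(centers, density, radius_scale)
    sigma = VDW_RADIUS_O * radius_scale
    dz = grid_spacing
    for frame in traj.frames:
        z = frame.coordinates[widx, 2]
        inside = (z >= z_lo - 4 * sigma) & (z <= z_hi + 4 * sigma)
        for z0 in z[inside]:
            g = np.exp(-0.5 * ((centers - z0) / sigma) ** 2)
            mass = g.sum() * dz
            if mass > 0:
                density += g / mass
    density /= traj.n_frames
    return DensityProfile(centers, density, radius_scale)


def _wire_present(
    oxy: np.ndarray, gate_z: tuple[float, float], cutoff: float
) -> bool:
    """Connectivity of the water-oxygen contact graph between z < gate bottom
    and z > gate top, via sparse connected components on KD-tree pairs."""
    gz0, gz1 = gate_z
    below = oxy[:, 2] < gz0
    above = oxy[:, 2] > gz1
    if not below.any() or not above.any():
        return False
    tree = cKDTree(oxy)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(oxy)
    if len(pairs) == 0:
        return False
    data = np.ones(len(pairs), dtype=bool)
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return bool(np.intersect1d(labels[below], labels[above]).size > 0)


def detect_water_wire(
    structure: Structure,
    gate_z_range: tuple[float, float] | None = None,
    oo_cutoff: float = OO_CUTOFF_DEFAULT,
) -> bool:
    """True iff a chain of water oxygens with successive O-O distances within
    ``oo_cutoff`` connects the region below the gate to the region above it."""
    if gate_z_range is None:
        gate_z_range = structure.meta.get("gate_z_range")
        if gate_z_range is None:
            raise ValueError("no gate_z_range given or in structure metadata")
    widx = water_oxygen_indices(structure)
    if widx.size == 0:
        return False
    oxy = structure.coordinates()[widx]
    return _wire_present(oxy, tuple(gate_z_range), oo_cutoff)


def wire_probability(
    traj: Trajectory,
    gate_z_range: tuple[float, float] | None = None,
    oo_cutoff: float = OO_CUTOFF_DEFAULT,
    window: float = 1.0,
) -> WireStats:
    """Percent of (windowed) frames containing a gate-spanning water wire."""
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    if gate_z_range is None:
        gate_z_range = traj.topology.meta.get("gate_z_range")
        if gate_z_range is None:
            raise ValueError("no gate_z_range given or in topology metadata")
    gate = tuple(gate_z_range)
    widx = water_oxygen_indices(traj.topology)
    start = int(round(traj.n_frames * (1.0 - window)))
    flags = np.zeros(traj.n_frames - start, dtype=bool)
    for k, i in enumerate(range(start, traj.n_frames)):
        if widx.size:
            flags[k] = _wire_present(traj.frames[i].coordinates[widx], gate, oo_cutoff)
    return WireStats(per_frame=flags, gate_z_range=gate)


def k_closest_waters(
    structure: Structure, ion: AtomRecord, k: int
) -> list[list[AtomRecord]]:
    """The k whole water residues nearest the ion, ranked by O-ion distance
    (ties broken by atom serial).  Returns fewer than k, with a warning, when
    the structure has fewer waters."""
    if k <= 0:
        raise ValueError("k must be positive")
    widx = water_oxygen_indices(structure)
    if widx.size == 0:
        raise ValueError("structure contains no waters")
    atoms = structure.atoms
    dists = np.array(
        [float(np.linalg.norm(atoms[i].position - ion.position)) for i in widx]
    )
    serials = np.array([atoms[i].serial for i in widx])
    order = np.lexsort((serials, dists))
    if widx.size < k:
        warnings.warn(f"only {widx.size} waters available, requested {k}")
    chosen = widx[order[:k]]
    residues = []
    for i in chosen:
        key = (atoms[i].chain_id, atoms[i].residue_number, atoms[i].residue_name)
        residues.append(
            [
                a
                for a in atoms
                if (a.chain_id, a.residue_number, a.residue_name) == key
            ]
        )
    return residues


def count_gate_crossings(
    traj: Trajectory,
    ion_selector="SOD",
    gate_z: float = 0.0,
    hysteresis: float = 1.0,
) -> list[CrossingEvents]:
    """Count full gate passages of each selected ion along z.

    A crossing requires the ion to move from above ``gate_z + hysteresis`` to
    below ``gate_z - hysteresis`` (or the reverse); excursions that stay
    within the +/- hysteresis band are jitter and are not counted.
    """
    if callable(ion_selector):
        sel = [i for i, a in enumerate(traj.topology.atoms) if ion_selector(a)]
    else:
        sel = [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.residue_name == ion_selector
        ]
    events = []
    for i in sel:
        z = np.array([f.coordinates[i, 2] for f in traj.frames])
        state = 0  # +1 above band, -1 below band, 0 undetermined
        crossings: list[int] = []
        for t, zt in enumerate(z):
            if zt > gate_z + hysteresis:
                if state == -1:
                    crossings.append(t)
                state = 1
            elif zt < gate_z - hysteresis:
                if state == 1:
                    crossings.append(t)
                state = -1
        events.append(
            CrossingEvents(
                ion_serial=traj.topology.atoms[i].serial, crossing_frames=crossings
            )
        )
    return events
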