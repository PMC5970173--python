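"""Inter-subunit contacts, ring metrics, and a simplified interaction-energy
comparator for relative Ca2+ affinities.

The Arg-Glu inter-subunit pair (Arg65-Glu426 in cASIC1 numbering) is scored
as a salt bridge: minimum carboxylate-oxygen to guanidinium-nitrogen distance
within a heavy-atom cutoff (4.0 A default).  Ring size for an acidic ring is
the circumdiameter of the circle through its three symmetry-related atoms.

Binding-energy frames follow the end-point scheme: the ion is the ligand and
the receptor is the protein plus the k = 5 waters closest to the ion; all
other solvent is stripped.  The energy itself is a documented *simplified*
molecular-mechanics comparator — Coulomb (constant or distance-dependent
dielectric) plus Lennard-Jones over receptor x ligand pairs.  No generalized
Born or surface-area terms are computed, so absolute binding free energies
are out of reach by construction; only relative comparisons between matched
systems are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_structures import (
    AtomRecord,
    Structure,
    Trajectory,
    WATER_RESIDUE_NAMES,
    pair_distance,
)
from .hydration_transport import k_closest_waters

__all__ = [
    "ContactResult",
    "RingMetrics",
    "ForceFieldParams",
    "EnergyDecomposition",
    "AffinityComparison",
    "COULOMB_CONSTANT",
    "detect_salt_bridge",
    "salt_bridge_occupancy",
    "ring_diameter",
    "site_separation",
    "prepare_gbsa_frames",
    "interaction_energy",
    "relative_affinity",
]

COULOMB_CONSTANT = 332.0636  # kcal A / (mol e^2)
SALT_BRIDGE_CUTOFF = 4.0  # A, heavy-atom convention

_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_CARBOXYLATE_C = {"ASP": "CG", "GLU": "CD"}


@dataclass(eq=False)
class ContactResult:
    acidic: tuple[str, int]  # (chain, residue number)
    basic: tuple[str, int]
    per_frame: np.ndarray  # boolean
    cutoff: float

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.per_frame)) if len(self.per_frame) else 0.0


@dataclass(eq=False)
class RingMetrics:
    position: int
    diameter: float  # A, circumdiameter
    centroid: np.ndarray


@dataclass(eq=False)
class ForceFieldParams:
    """Per-atom nonbonded parameters keyed by (residue_name, atom_name).

    ``lj`` maps to (r_min, well_depth): r_min is the pair separation at the
    LJ minimum for a like pair (combined by arithmetic mean), well depth in
    kcal/mol (combined geometrically).  ``dielectric`` is a constant, or with
    ``distance_dependent=True``, eps(r) = dielectric * r.
    """

    charges: dict[tuple[str, str], float] = field(default_factory=dict)
    lj: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    dielectric: float = 1.0
    distance_dependent: bool = False

    def charge_of(self, atom: AtomRecord) -> float:
        key = (atom.residue_name, atom.name)
        if key in self.charges:
            return self.charges[key]
        if atom.partial_charge is not None:
            return atom.partial_charge
        raise KeyError(f"no charge for {atom.residue_name}/{atom.name}")

    def lj_of(self, atom: AtomRecord) -> tuple[float, float]:
        return self.lj.get((atom.residue_name, atom.name), (0.0, 0.0))

    def epsilon(self, r: float) -> float:
        return self.dielectric * r if self.distance_dependent else self.dielectric


@dataclass(eq=False)
class EnergyDecomposition:
    coulomb: float
    lennard_jones: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lennard_jones


@dataclass(eq=False)
class AffinityComparison:
    mean_energy_a: float
    mean_energy_b: float
    percent_difference: float


def _residue_atoms(structure: Structure, chain: str, resnum: int) -> list[AtomRecord]:
    return [
        a
        for a in structure.atoms
        if a.chain_id == chain and a.residue_number == resnum
    ]


def detect_salt_bridge(
    structure: Structure,
    acidic: tuple[str, int],
    basic: tuple[str, int],
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> bool:
    """True iff the minimum carboxylate-O to guanidinium/amine-N distance is
    within the heavy-atom cutoff."""
    a_atoms = _residue_atoms(structure, *acidic)
    b_atoms = _residue_atoms(structure, *basic)
    if not a_atoms or not b_atoms:
        raise ValueError(f"residue {acidic if not a_atoms else basic} not found")
    a_res = a_atoms[0].residue_name
    b_res = b_atoms[0].residue_name
    o_names = _ACIDIC_O.get(a_res)
    n_names = _BASIC_N.get(b_res)
    if o_names is None:
        raise ValueError(f"{a_res}{acidic[1]} is not an acidic residue")
    if n_names is None:
        raise ValueError(f"{b_res}{basic[1]} is not a basic residue")
    o_atoms = [a for a in a_atoms if a.name in o_names]
    n_atoms = [a for a in b_atoms if a.name in n_names]
    if not o_atoms:
        raise ValueError(f"{a_res}{acidic[1]}: side-chain oxygens missing")
    if not n_atoms:
        raise ValueError(f"{b_res}{basic[1]}: side-chain nitrogens missing")
    dmin = min(
        pair_distance(o.position, n.position, structure.box)
        for o in o_atoms
        for n in n_atoms
    )
    return dmin <= cutoff


def salt_bridge_occupancy(
    traj: Trajectory,
    acidic: tuple[str, int],
    basic: tuple[str, int],
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> ContactResult:
    """Per-frame salt-bridge presence and its occupancy fraction."""
    flags = np.array(
        [
            detect_salt_bridge(traj.structure_at(i), acidic, basic, cutoff)
            for i in range(traj.n_frames)
        ],
        dtype=bool,
    )
    return ContactResult(acidic=acidic, basic=basic, per_frame=flags, cutoff=cutoff)


def ring_diameter(
    structure: Structure, position: int, atom_name: str = "CD"
) -> RingMetrics:
    """Circumdiameter of the circle through the three symmetry-related ring
    atoms (default: glutamate carboxylate carbons)."""
    from .core_structures import select_ring

    ring = select_ring(structure, position, atom_name)
    p = ring.coordinates()
    a = np.linalg.norm(p[1] - p[2])
    b = np.linalg.norm(p[0] - p[2])
    c = np.linalg.norm(p[0] - p[1])
    cross = np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
    if cross < 1e-12:
        raise ValueError(f"ring atoms at position {position} are collinear")
    area = 0.5 * cross
    diameter = float(a * b * c / (2.0 * area))
    return RingMetrics(
        position=position, diameter=diameter, centroid=p.mean(axis=0)
    )


def site_separation(
    structure: Structure,
    site_a: list[tuple[str, int]],
    site_b: list[tuple[str, int]],
    atom_rule: str = "carboxylate_carbon",
) -> float:
    """Distance between the centroids of two residue sets.

    ``atom_rule="carboxylate_carbon"`` uses the side-chain carboxylate carbon
    (CG for Asp, CD for Glu) and falls back to Calpha for other residues;
    ``atom_rule="CA"`` uses Calphas throughout.
    """

    def centroid(site: list[tuple[str, int]]) -> np.ndarray:
        points = []
        for chain, resnum in site:
            atoms = _residue_atoms(structure, chain, resnum)
            if not atoms:
                raise ValueError(f"residue {chain}/{resnum} not found")
            resname = atoms[0].residue_name
            wanted = (
                _CARBOXYLATE_C.get(resname, "CA")
                if atom_rule == "carboxylate_carbon"
                else atom_rule
            )
            match = [a for a in atoms if a.name == wanted] or [
                a for a in atoms if a.name == "CA"
            ]
            if not match:
                raise ValueError(f"no {wanted} or CA atom in {chain}/{resnum}")
            points.append(match[0].position)
        if not points:
            raise ValueError("empty residue selection")
        return np.mean(points, axis=0)

    return float(np.linalg.norm(centroid(site_a) - centroid(site_b)))


def prepare_gbsa_frames(
    traj: Trajectory, ion_selector="CAL", k: int = 5
):
    """Yield (receptor, ligand) structures per frame for end-point energy
    estimates: receptor = protein + the k waters closest to the ion, ligand =
    the ion alone; all other waters and ions are stripped."""
    for i in range(traj.n_frames):
        s = traj.structure_at(i)
        if callable(ion_selector):
            ions = [a for a in s.atoms if ion_selector(a)]
        else:
            ions = [a for a in s.atoms if a.residue_name == ion_selector]
        if not ions:
            raise ValueError(f"ion not found in frame {i}")
        ion = ions[0]
        kept_waters: set[int] = set()
        if k > 0:
            for res in k_closest_waters(s, ion, k):
                kept_waters.update(a.serial for a in res)
        receptor_atoms = [
            a
            for a in s.atoms
            if a is not ion
            and not (a.residue_name in WATER_RESIDUE_NAMES and a.serial not in kept_waters)
            and a.residue_name not in ("SOD", "CLA")
        ]
        receptor = Structure(atoms=receptor_atoms, box=s.box, meta=dict(s.meta))
        ligand = Structure(atoms=[ion], box=s.box)
        yield receptor, ligand


def interaction_energy(
    receptor: Structure, ligand: Structure, params: ForceFieldParams
) -> EnergyDecomposition:
    """Pairwise receptor x ligand molecular-mechanics interaction energy.

    coulomb = sum 332.0636 q_i q_j / (eps(r) r); LJ in the r_min/well-depth
    form eps_ij [ (r_min/r)^12 - 2 (r_min/r)^6 ].
    """
    missing = []
    for a in receptor.atoms + ligand.atoms:
        try:
            params.charge_of(a)
        except KeyError:
            missing.append(f"{a.residue_name}/{a.name}")
    if missing:
        raise ValueError(f"missing charges for atoms: {sorted(set(missing))}")
    coulomb = 0.0
    lj = 0.0
    for i in receptor.atoms:
        qi = params.charge_of(i)
        rmin_i, eps_i = params.lj_of(i)
        for j in ligand.atoms:
            r = pair_distance(i.position, j.position, receptor.box)
            if r == 0:
                raise ValueError(
                    f"zero distance between atoms {i.serial} and {j.serial}"
                )
            coulomb += COULOMB_CONSTANT * qi * params.charge_of(j) / (
                params.epsilon(r) * r
            )
            rmin_j, eps_j = params.lj_of(j)
            eps_ij = np.sqrt(eps_i * eps_j)
            if eps_ij > 0:
                rmin_ij = 0.5 * (rmin_i + rmin_j)
                frac6 = (rmin_ij / r) ** 6
                lj += eps_ij * (frac6 * frac6 - 2.0 * frac6)
    return EnergyDecomposition(coulomb=coulomb, lennard_jones=lj)


def relative_affinity(
    energies_a: np.ndarray, energies_b: np.ndarray
) -> AffinityComparison:
    """Percent difference of mean interaction energies between two systems:
    100 (<E_B> - <E_A>) / |<E_A>|.  With the more-negative-is-stronger sign
    convention, a *negative* percent difference means B binds more strongly;
    the magnitude matches the "x% higher affinity" comparison form.
    """
    ea = float(np.mean(energies_a))
    eb = float(np.mean(energies_b))
    if ea == 0:
        raise ValueError("mean energy of system A is zero")
    return AffinityComparison(
        mean_energy_a=ea,
        mean_energy_b=eb,
        percent_difference=100.0 * (eb - ea) / abs(ea),
    )
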