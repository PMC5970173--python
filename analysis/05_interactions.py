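#!/usr/bin/env python
"""Inter-subunit contacts and the simplified relative-affinity comparison.

Scores an Arg-Glu inter-subunit salt bridge over a synthetic trajectory in
which the pair engages in the expanded (intermediate-like) frames only,
measures the acidic-ring circumdiameter and the separation between an
extracellular acidic pocket and the gate, prepares binding-energy frames
(ion as ligand, protein + 5 closest waters as receptor), and compares the
simplified interaction energies of a 7-carboxylate-oxygen site against a
6-oxygen site: the extra glutamate strengthens Ca2+ binding.
"""

import json
import math
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))

from poreblock.core_structures import AtomRecord, Frame, Structure, Trajectory
from poreblock.interactions_energetics import (
    ForceFieldParams,
    interaction_energy,
    prepare_gbsa_frames,
    relative_affinity,
    ring_diameter,
    salt_bridge_occupancy,
    site_separation,
)
from poreblock.synthetic_data import (
    CoordinationFixtureSpec,
    MUTANT_SITE_ROSTER,
    WILD_TYPE_SITE_ROSTER,
    build_coordination_fixture,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# carboxylate oxygen and water charges (CHARMM-like magnitudes), ion +2
CHARGES = {
    ("ASP", "OD1"): -0.76, ("ASP", "OD2"): -0.76, ("ASP", "CG"): 0.62,
    ("GLU", "OE1"): -0.76, ("GLU", "OE2"): -0.76, ("GLU", "CD"): 0.62,
    ("HOH", "O"): -0.834,
    ("CAL", "CA"): 2.0,
}


def bridge_trajectory(seed: int, n_frames: int = 40) -> Trajectory:
    """Glu426/Arg65 pair engaged (3 A) in even frames, apart (8 A) in odd."""
    def coords(d):
        return np.array(
            [[0, 0, 0], [0, 1.2, 0], [d, 0, 0], [d + 1.0, 1.0, 0], [d + 1.5, -1, 0]],
            dtype=float,
        )

    atoms = [
        AtomRecord(1, "OE1", "O", "GLU", 426, "A", np.zeros(3)),
        AtomRecord(2, "OE2", "O", "GLU", 426, "A", np.zeros(3)),
        AtomRecord(3, "NH1", "N", "ARG", 65, "B", np.zeros(3)),
        AtomRecord(4, "NH2", "N", "ARG", 65, "B", np.zeros(3)),
        AtomRecord(5, "NE", "N", "ARG", 65, "B", np.zeros(3)),
    ]
    topo = Structure(atoms=atoms).with_coordinates(coords(3.0))
    frames = [
        Frame(coordinates=coords(3.0 if t % 2 == 0 else 8.0), time_index=t)
        for t in range(n_frames)
    ]
    return Trajectory(topology=topo, frames=frames)


def site_energies(geometry, roster, seed, n_frames=25):
    """Mean simplified interaction energy of the ion with its site over
    jittered shell frames, after the 5-closest-water receptor preparation."""
    params = ForceFieldParams(charges=CHARGES, dielectric=4.0)
    energies = []
    topo = build_coordination_fixture(
        CoordinationFixtureSpec(geometry, roster, 2.4, 4.0, seed)
    )
    frames = [
        Frame(
            coordinates=build_coordination_fixture(
                CoordinationFixtureSpec(geometry, roster, 2.4, 4.0, seed + t)
            ).coordinates(),
            time_index=t,
        )
        for t in range(n_frames)
    ]
    traj = Trajectory(topology=topo, frames=frames)
    for receptor, ligand in prepare_gbsa_frames(traj, "CAL", k=5):
        energies.append(interaction_energy(receptor, ligand, params).total)
    return np.array(energies)


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    report = {}

    contact = salt_bridge_occupancy(bridge_trajectory(seed), ("A", 426), ("B", 65))
    report["arg_glu_occupancy"] = contact.occupancy
    print(f"Arg65-Glu426 salt-bridge occupancy: {contact.occupancy:.2f}")

    # acidic ring of published size: circumradius 12.5 A -> diameter 25 A
    ring_atoms = [
        AtomRecord(
            i + 1, "CD", "C", "GLU", 426, "ABC"[i],
            np.array([12.5 * math.cos(a), 12.5 * math.sin(a), 0.0]),
        )
        for i, a in enumerate((0.0, 2 * math.pi / 3, 4 * math.pi / 3))
    ]
    ring = ring_diameter(Structure(atoms=ring_atoms), 426)
    report["glu426_ring_diameter_A"] = ring.diameter
    print(f"Glu426 ring circumdiameter: {ring.diameter:.1f} A")

    # acidic pocket 55 A above the gate ring along the pore axis
    pocket = Structure(
        atoms=ring_atoms
        + [
            AtomRecord(10, "CG", "C", "ASP", 433, "A", np.array([4.0, 0.0, -55.0])),
            AtomRecord(11, "CG", "C", "ASP", 433, "B", np.array([-2.0, 3.46, -55.0])),
            AtomRecord(12, "CG", "C", "ASP", 433, "C", np.array([-2.0, -3.46, -55.0])),
        ]
    )
    sep = site_separation(pocket, [("A", 426), ("B", 426), ("C", 426)],
                          [("A", 433), ("B", 433), ("C", 433)])
    report["pocket_to_gate_separation_A"] = sep
    print(f"acidic-pocket to gate separation: {sep:.1f} A")

    e_mut = site_energies("pentagonal_bipyramidal", MUTANT_SITE_ROSTER, seed)
    e_wt = site_energies("octahedral", WILD_TYPE_SITE_ROSTER, seed + 1000)
    cmp = relative_affinity(e_wt, e_mut)
    report["mean_energy_wild_type_kcal_mol"] = cmp.mean_energy_a
    report["mean_energy_mutant_kcal_mol"] = cmp.mean_energy_b
    report["relative_affinity_percent"] = cmp.percent_difference
    print(
        f"mean site energies (kcal/mol): wild type {cmp.mean_energy_a:.1f}, "
        f"mutant {cmp.mean_energy_b:.1f} -> mutant binds "
        f"{abs(cmp.percent_difference):.0f}% more strongly"
    )

    (RESULTS / "interactions.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'interactions.json'}")


if __name__ == "__main__":
    main()
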