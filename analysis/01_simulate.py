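#!/usr/bin/env python
"""Generate the synthetic study systems.

Writes the pseudo-pore scaffold topology, one trajectory per channel system
(wild type / mutant, with and without Ca2+), and one dose-response CSV per
recorded condition.  Trajectories (binary DCD) go under scratch/fixtures/;
the small CSVs go under results/.  All later drivers regenerate the same
systems in memory from the shared specs, so this step is for inspection and
for feeding the files to the command-line interface.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_conditions import (
    MARKER_RADII,
    dose_response_spec,
    DOSE_RESPONSE_CONDITIONS,
    trajectory_spec,
    AREA_TARGETS,
)

from poreblock.core_structures import write_structure, write_trajectory
from poreblock.synthetic_data import (
    build_channel_scaffold,
    simulate_dose_response,
    simulate_trajectory,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    scaffold = build_channel_scaffold(MARKER_RADII)
    for i, system in enumerate(AREA_TARGETS):
        traj = simulate_trajectory(scaffold, trajectory_spec(system, seed + i))
        write_structure(traj.topology, SCRATCH / f"{system}_topology.pdb")
        write_trajectory(traj, SCRATCH / f"{system}.dcd")
        print(f"{system}: {traj.n_frames} frames, {traj.topology.n_atoms} atoms")

    for j, condition in enumerate(DOSE_RESPONSE_CONDITIONS):
        data = simulate_dose_response(dose_response_spec(condition, 100 + seed + j))
        out = RESULTS / f"dose_response_{condition}.csv"
        data.to_csv(out, index=False)
        print(f"{condition}: {data.cell_id.nunique()} cells -> {out.name}")


if __name__ == "__main__":
    main()
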