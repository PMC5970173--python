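#!/usr/bin/env python
"""Pore-aperture analysis: Asp433-ring triangle-area distributions.

For each channel system the per-frame area of the triangle through the
three symmetry-related Asp433 Calphas is histogrammed over the last 30% of
frames; the modal peak areas are compared between Ca2+-bound and Ca2+-free
conditions.  With the study conditions used here the mutant pore peak grows
by roughly 167% on Ca2+ removal and the wild-type pore by roughly 68%.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_conditions import MARKER_RADII, trajectory_spec, AREA_TARGETS

from poreblock.pore_geometry import area_distribution, area_series, percent_peak_change
from poreblock.synthetic_data import build_channel_scaffold, simulate_trajectory

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    scaffold = build_channel_scaffold(MARKER_RADII)
    dists = {}
    report = {"peak_area_A2": {}}
    for i, system in enumerate(AREA_TARGETS):
        traj = simulate_trajectory(scaffold, trajectory_spec(system, seed + i))
        series = area_series(traj, 433)
        dists[system] = area_distribution(series, analysis_window=0.3)
        report["peak_area_A2"][system] = dists[system].peak_area
        print(f"{system}: peak area {dists[system].peak_area:.1f} A^2")

    report["percent_peak_change"] = {
        "mutant_on_Ca_removal": percent_peak_change(
            dists["mutant_1Ca"], dists["mutant_0Ca"]
        ),
        "wild_type_on_Ca_removal": percent_peak_change(
            dists["wild_type_1Ca"], dists["wild_type_0Ca"]
        ),
    }
    for k, v in report["percent_peak_change"].items():
        print(f"{k}: {v:+.0f}%")

    (RESULTS / "pore_areas.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'pore_areas.json'}")


if __name__ == "__main__":
    main()
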