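"""Shared study conditions for the analysis drivers.

These constants define the synthetic stand-ins for the four simulated
channel systems (wild type and pore mutant, each with and without a bound
Ca2+) and the six recorded electrophysiology conditions.  The dose-response
parameter sets are the published per-channel Hill parameters; the synthetic
trajectory area targets encode the relative pore widening observed between
Ca2+-bound and Ca2+-free systems (the mutant pore peak area grows ~2.67x on
Ca2+ removal, the wild type ~1.68x).
"""

from poreblock.synthetic_data import DoseResponseSpec, TrajectorySpec

MARKER_RADII = {429: 8.0, 433: 5.0, 436: 7.0}

# peak triangle-area targets (A^2) for the Asp433 ring, per system
AREA_TARGETS = {
    "mutant_1Ca": 30.0,
    "mutant_0Ca": 30.0 * 2.67,
    "wild_type_1Ca": 30.0,
    "wild_type_0Ca": 30.0 * 1.68,
}
AREA_NOISE_SD = 2.5  # A^2, frame-to-frame breathing
N_FRAMES = 600  # light-weight stand-in for a production trajectory


def trajectory_spec(system: str, seed: int, wire_frames=frozenset()) -> TrajectorySpec:
    return TrajectorySpec(
        n_frames=N_FRAMES,
        area_series={433: (AREA_TARGETS[system], AREA_NOISE_SD)},
        ion_present=system.endswith("1Ca"),
        wire_frames=wire_frames,
        n_sodium=1,
        seed=seed,
    )


# published Hill parameters: (pH50, nH, n cells); amplitudes in pA
DOSE_RESPONSE_CONDITIONS = {
    "cASIC1_plusCa": (6.90, 4.07, 5),
    "cASIC1_minusCa": (7.01, 2.05, 5),
    "rASIC3_plusCa": (6.86, 3.54, 4),
    "rASIC3_minusCa": (7.32, 1.48, 4),
    "G429E_plusCa": (6.98, 3.96, 9),
    "G429E_minusCa": (7.42, 4.99, 6),
}
PH_GRID = (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.2, 7.4, 7.6, 7.8, 8.0)
NOISE_SD = 0.03  # fraction of Imax per measurement


def dose_response_spec(condition: str, seed: int) -> DoseResponseSpec:
    ph50, nh, n_cells = DOSE_RESPONSE_CONDITIONS[condition]
    return DoseResponseSpec(
        pH50=ph50, nH=nh, Imax=2000.0, pH_grid=PH_GRID,
        noise_sd=NOISE_SD, n_cells=n_cells,
        calcium_mM=1.0 if condition.endswith("plusCa") else 0.0,
        seed=seed,
    )
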