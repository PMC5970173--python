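"""Pore-mouth geometry: triangle areas of symmetry-related residue rings.

The channel pore aperture is tracked as the area of the triangle formed by
the three symmetry-related Calpha atoms of a pore-lining residue (positions
429, 433 and 436).  Per-frame areas are summarised as a probability
distribution over an analysis window; "peak area" is the modal bin centre,
and pore widening between conditions is quoted as the percent change in
that peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .core_structures import Trajectory, select_ring

__all__ = [
    "AreaSeries",
    "AreaDistribution",
    "triangle_area",
    "area_series",
    "area_distribution",
    "percent_peak_change",
]


def triangle_area(p1, p2, p3) -> float:
    """Area of the triangle spanned by three 3-vectors: 0.5 |(p2-p1)x(p3-p1)|."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    return 0.5 * float(np.linalg.norm(np.cross(p2 - p1, p3 - p1)))


@dataclass(eq=False)
class AreaSeries:
    position: int
    atom_name: str
    values: np.ndarray  # A^2, one per frame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("areas must be non-negative")


@dataclass(eq=False)
class AreaDistribution:
    bin_edges: np.ndarray
    probabilities: np.ndarray
    peak_area: float
    reference_lines: dict[str, float] | None = None

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


def area_series(traj: Trajectory, position: int, atom_name: str = "CA") -> AreaSeries:
    """Per-frame ring triangle area for one marker position, frame order kept."""
    ring = select_ring(traj.topology, position, atom_name)
    by_id = {id(at): i for i, at in enumerate(traj.topology.atoms)}
    idx = [by_id[id(a)] for a in ring.atoms]
    values = np.array(
        [
            triangle_area(
                f.coordinates[idx[0]], f.coordinates[idx[1]], f.coordinates[idx[2]]
            )
            for f in traj.frames
        ]
    )
    return AreaSeries(position=position, atom_name=atom_name, values=values)


def area_distribution(
    series: AreaSeries,
    n_bins: int | str = "fd",
    analysis_window: float = 0.3,
    method: str = "histogram",
    reference_lines: dict[str, float] | None = None,
) -> AreaDistribution:
    """Normalised area distribution over the last ``analysis_window`` fraction
    of frames (default 30%, mirroring analysis of the final stretch of a
    production run), with the peak at the modal bin centre.

    ``n_bins`` is a bin count or a numpy binning rule (default
    Freedman-Diaconis); ``method="kde"`` evaluates a Gaussian KDE on the same
    grid instead of counting.
    """
    if not 0 < analysis_window <= 1:
        raise ValueError("analysis_window must be in (0, 1]")
    values = series.values
    start = int(round(len(values) * (1.0 - analysis_window)))
    window = values[start:]
    if len(window) < 10:
        raise ValueError(
            f"only {len(window)} frames in the analysis window; need >= 10"
        )
    edges = np.histogram_bin_edges(window, bins=n_bins)
    if method == "histogram":
        counts, edges = np.histogram(window, bins=edges)
        probs = counts / counts.sum()
    elif method == "kde":
        if np.ptp(window) == 0:
            counts, edges = np.histogram(window, bins=edges)
            probs = counts / counts.sum()
        else:
            kde = gaussian_kde(window)
            centers = 0.5 * (edges[:-1] + edges[1:])
            dens = kde(centers)
            probs = dens / dens.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = float(centers[int(np.argmax(probs))])
    return AreaDistribution(
        bin_edges=edges, probabilities=probs, peak_area=peak,
        reference_lines=reference_lines,
    )


def percent_peak_change(dist_ref: AreaDistribution, dist_alt: AreaDistribution) -> float:
    """Percent change of the peak area from reference to alternative:
    100 * (peak_alt - peak_ref) / peak_ref."""
    if dist_ref.peak_area == 0:
        raise ValueError("reference peak area is zero")
    return 100.0 * (dist_alt.peak_area - dist_ref.peak_area) / dist_ref.peak_area
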