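"""Whole-cell electrophysiology statistics.

Covers the analysis chain for proton dose-response experiments on ASIC
channels: per-cell normalisation of peak currents to a control response,
percent reduction between groups, Hill fitting of pH activation curves,
extra-sum-of-squares F tests for comparing curves, and two-sample t tests
reconstructed from summary statistics (mean, SEM, n).

The activation model is the Hill curve on the pH scale,

    I(pH) = Imax / (1 + 10^(nH (pH - pH50))),

which gives half-maximal current at pH50 and slope factor nH (equivalent to
a Hill function of proton concentration).  Fitting is deterministic: a
coarse (pH50, nH) grid with the amplitude profiled out linearly picks the
start for a single Levenberg-Marquardt refinement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import hill_response

__all__ = [
    "GroupSummary",
    "HillFit",
    "FTestResult",
    "TTestResult",
    "percent_of_control",
    "percent_reduction",
    "fit_hill",
    "extra_ss_f_test",
    "compare_hill_fits",
    "t_test_from_summary",
]


@dataclass(eq=False)
class GroupSummary:
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass(eq=False)
class HillFit:
    pH50: float
    pH50_se: float
    nH: float
    nH_se: float
    Imax: float
    rss: float
    dof: int
    n_points: int


@dataclass(eq=False)
class FTestResult:
    statistic: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(eq=False)
class TTestResult:
    statistic: float
    df: float
    p_value: float


def percent_of_control(test_peaks, control_peaks) -> GroupSummary:
    """Per-cell percent of control (100 * test / control), summarised as
    mean, SEM (sd / sqrt(n)) and n."""
    test = np.asarray(test_peaks, dtype=float)
    control = np.asarray(control_peaks, dtype=float)
    if test.shape != control.shape:
        raise ValueError("test and control must be paired per cell")
    zero = np.nonzero(control == 0)[0]
    if zero.size:
        raise ValueError(f"zero control response for cell index {zero[0]}")
    pct = 100.0 * test / control
    n = pct.size
    sem = float(np.std(pct, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(mean=float(np.mean(pct)), sem=sem, n=n)


def percent_reduction(group_ref: GroupSummary, group_alt: GroupSummary) -> float:
    """Percent of the reference response eliminated in the alternative group:
    100 * (mean_ref - mean_alt) / mean_ref."""
    if group_ref.mean == 0:
        raise ValueError("reference group mean is zero")
    return 100.0 * (group_ref.mean - group_alt.mean) / group_ref.mean


# ---------------------------------------------------------------------------
# Hill fitting

_PH50_GRID = np.arange(6.0, 8.01, 0.2)
_NH_GRID = np.array([0.5, 1.0, 2.0, 4.0, 8.0])


def _best_grid_start(ph: np.ndarray, current: np.ndarray) -> tuple[float, float, float]:
    """Profile the amplitude analytically on a (pH50, nH) grid and return the
    best (pH50, nH, Imax) start."""
    best = (np.inf, 7.0, 2.0, float(current.max() or 1.0))
    for p50, nh in itertools.product(_PH50_GRID, _NH_GRID):
        f = hill_response(ph, p50, nh, 1.0)
        denom = float(f @ f)
        if denom == 0:
            continue
        imax = float(f @ current) / denom
        rss = float(np.sum((current - imax * f) ** 2))
        if rss < best[0]:
            best = (rss, p50, nh, imax)
    return best[1], best[2], best[3]


def fit_hill(
    data: pd.DataFrame,
    imax_fixed: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of pooled dose-response records.

    ``data`` needs columns ``pH`` and ``current_pA`` (``simulate_dose_response``
    output or a CSV with the same layout).  ``imax_fixed`` pins the amplitude
    (use 1.0 for pre-normalised responses); otherwise Imax is free.  The fit
    is deterministic: grid start + one bounded least-squares refinement.
    Raises on flat or asymptote-only (unidentifiable) data.
    """
    ph = np.asarray(data["pH"], dtype=float)
    current = np.asarray(data["current_pA"], dtype=float)
    if not np.all(np.isfinite(current)):
        raise ValueError("non-finite currents")
    if np.unique(ph).size < 4:
        raise ValueError("need >= 4 distinct pH values")
    span = float(current.max() - current.min())
    if span == 0:
        raise ValueError("flat dose-response data: Hill parameters unidentifiable")
    # asymptote-only data carry no slope information
    lo, hi = current.min(), current.max()
    interior = (current > lo + 0.02 * span) & (current < hi - 0.02 * span)
    if not interior.any():
        raise ValueError(
            "all responses sit on the asymptotes: pH50/nH unidentifiable"
        )

    p50_0, nh_0, imax_0 = _best_grid_start(ph, current)

    if imax_fixed is None:
        def residuals(theta):
            p50, nh, imax = theta
            return hill_response(ph, p50, nh, imax) - current

        x0 = np.array([p50_0, nh_0, imax_0])
        bounds = ([4.0, 1e-3, -np.inf], [9.0, 50.0, np.inf])
    else:
        def residuals(theta):
            p50, nh = theta
            return hill_response(ph, p50, nh, imax_fixed) - current

        x0 = np.array([p50_0, nh_0])
        bounds = ([4.0, 1e-3], [9.0, 50.0])

    sol = optimize.least_squares(residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"Hill fit did not converge: {sol.message}")
    rss = float(np.sum(sol.fun**2))
    n = ph.size
    n_params = x0.size
    dof = n - n_params
    # standard errors from the Jacobian at the solution
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof if dof > 0 else np.nan)
        ses = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        ses = np.full(n_params, np.nan)
    p50, nh = float(sol.x[0]), float(sol.x[1])
    imax = float(imax_fixed if imax_fixed is not None else sol.x[2])
    return HillFit(
        pH50=p50,
        pH50_se=float(ses[0]),
        nH=nh,
        nH_se=float(ses[1]),
        Imax=imax,
        rss=rss,
        dof=dof,
        n_points=n,
    )


def extra_ss_f_test(fit_shared: HillFit, fits_separate: list[HillFit]) -> FTestResult:
    """Extra-sum-of-squares F test of one shared curve against separate
    curves per dataset: F = ((RSS_sh - RSS_sep)/(df_sh - df_sep)) /
    (RSS_sep / df_sep), p from the F distribution."""
    rss_sep = sum(f.rss for f in fits_separate)
    dof_sep = sum(f.dof for f in fits_separate)
    rss_sh = fit_shared.rss
    dof_sh = fit_shared.dof
    if dof_sh <= dof_sep:
        raise ValueError("shared model must have more residual dof (nested models)")
    # both models fit to numerical precision: no evidence for separate curves
    floor = (1e-8 * max(abs(fit_shared.Imax), 1.0)) ** 2 * fit_shared.n_points
    if rss_sh < floor and rss_sep < floor:
        rss_sh = rss_sep = 0.0
    if rss_sep == 0:
        if rss_sh == rss_sep:
            return FTestResult(
                statistic=0.0, df_num=dof_sh - dof_sep, df_den=dof_sep, p_value=1.0
            )
        return FTestResult(
            statistic=np.inf, df_num=dof_sh - dof_sep, df_den=dof_sep, p_value=0.0
        )
    df_num = dof_sh - dof_sep
    f_stat = ((rss_sh - rss_sep) / df_num) / (rss_sep / dof_sep)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_num, dof_sep))
    return FTestResult(statistic=float(f_stat), df_num=df_num, df_den=dof_sep, p_value=p)


def compare_hill_fits(
    data_a: pd.DataFrame, data_b: pd.DataFrame, imax_fixed: float | None = None
) -> FTestResult:
    """Convenience wrapper: fit each dataset and their pool, then run the
    extra-sum-of-squares F test for curve equality."""
    fit_a = fit_hill(data_a, imax_fixed=imax_fixed)
    fit_b = fit_hill(data_b, imax_fixed=imax_fixed)
    pooled = pd.concat([data_a, data_b], ignore_index=True)
    fit_sh = fit_hill(pooled, imax_fixed=imax_fixed)
    return extra_ss_f_test(fit_sh, [fit_a, fit_b])


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "student"
) -> TTestResult:
    """Unpaired two-sample t test from summary statistics.

    ``student`` pools variances (sd recovered as sem * sqrt(n)); ``welch``
    uses the Welch-Satterthwaite degrees of freedom.  Two-sided p.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both groups")
    var_a = (a.sem * np.sqrt(a.n)) ** 2
    var_b = (b.sem * np.sqrt(b.n)) ** 2
    if variant == "student":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * var_a + (b.n - 1) * var_b) / df
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    elif variant == "welch":
        se2_a = var_a / a.n
        se2_b = var_b / b.n
        se = np.sqrt(se2_a + se2_b)
        df = (se2_a + se2_b) ** 2 / (
            se2_a**2 / (a.n - 1) + se2_b**2 / (b.n - 1)
        )
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se == 0:
        t = 0.0
        p = 1.0
    else:
        t = (a.mean - b.mean) / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(statistic=float(t), df=float(df), p_value=p)
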