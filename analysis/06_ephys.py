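#!/usr/bin/env python
"""Electrophysiology statistics over the six recorded conditions.

Fits the Hill activation curve to each synthetic dose-response dataset
(generated from the published per-channel parameters with per-cell noise),
runs the extra-sum-of-squares F test for the with- vs without-Ca2+
comparison of each channel, and reproduces the summary-statistics analyses:
percent-of-control normalisation, the ~62% loss of Ca2+ sensitivity in the
glycine-substituted rat channel, and the pooled t test between wild-type
and mutant relative currents.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_conditions import DOSE_RESPONSE_CONDITIONS, dose_response_spec

from poreblock.ephys_stats import (
    GroupSummary,
    compare_hill_fits,
    fit_hill,
    percent_reduction,
    t_test_from_summary,
)
from poreblock.synthetic_data import simulate_dose_response

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# published relative-current summaries at pH 7.4 / 0 Ca2+ (% of control)
CA_RESPONSE = {
    "cASIC1": GroupSummary(2.8, 1.1, 13),
    "cASIC1_G429E": GroupSummary(13.0, 3.1, 8),
    "rASIC3": GroupSummary(73.0, 5.8, 11),
    "rASIC3_E435G": GroupSummary(28.0, 5.6, 6),
}


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    report = {"hill_fits": {}, "f_tests": {}}

    datasets = {}
    for j, condition in enumerate(DOSE_RESPONSE_CONDITIONS):
        data = simulate_dose_response(dose_response_spec(condition, 100 + seed + j))
        datasets[condition] = data
        fit = fit_hill(data)
        true_p50, true_nh, _ = DOSE_RESPONSE_CONDITIONS[condition]
        report["hill_fits"][condition] = {
            "pH50": round(fit.pH50, 3), "pH50_se": round(fit.pH50_se, 3),
            "nH": round(fit.nH, 2), "nH_se": round(fit.nH_se, 2),
            "true_pH50": true_p50, "true_nH": true_nh,
        }
        print(
            f"{condition}: pH50 {fit.pH50:.2f} +/- {fit.pH50_se:.2f} "
            f"(true {true_p50}), nH {fit.nH:.2f} +/- {fit.nH_se:.2f} "
            f"(true {true_nh})"
        )

    for channel in ("cASIC1", "rASIC3", "G429E"):
        ft = compare_hill_fits(
            datasets[f"{channel}_plusCa"], datasets[f"{channel}_minusCa"]
        )
        report["f_tests"][channel] = {
            "F": round(ft.statistic, 2), "df": [ft.df_num, ft.df_den],
            "p": ft.p_value,
        }
        print(f"{channel} +/-Ca curves: F = {ft.statistic:.1f}, p = {ft.p_value:.2e}")

    red = percent_reduction(CA_RESPONSE["rASIC3"], CA_RESPONSE["rASIC3_E435G"])
    report["rASIC3_E435G_percent_reduction"] = round(red, 1)
    print(f"E435G removes {red:.0f}% of the rASIC3 Ca2+ sensitivity")

    tt = t_test_from_summary(
        CA_RESPONSE["cASIC1"], CA_RESPONSE["cASIC1_G429E"], variant="student"
    )
    report["cASIC1_vs_G429E_t_test"] = {
        "t": round(tt.statistic, 2), "df": tt.df, "p": tt.p_value,
    }
    print(f"cASIC1 vs G429E relative current: t = {tt.statistic:.2f}, "
          f"p = {tt.p_value:.1e}")

    (RESULTS / "ephys.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'ephys.json'}")


if __name__ == "__main__":
    main()
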