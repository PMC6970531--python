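#!/usr/bin/env python
"""Quantify the clamp-rotation range of three simulated particle ensembles.

Reads the eigenvalue tables from step 01 (or regenerates them), runs the
Gaussian-fit / tercile-binning / 98%-range pipeline, and tabulates the
tercile rotation (theta_bin) and extrapolated 98% range (theta_98) per
ensemble.  The free holoenzyme shows the widest range, the regulator-bound
enzyme a narrower one, and the promoter-bound open complex the narrowest —
the restriction ordering the multibody analysis is designed to detect.
Writes results/clamp_ranges.csv.
"""

import json
from pathlib import Path

from rnapconf.heterogeneity import clamp_range_report, load_eigenvalues
from rnapconf.synthetic import simulate_eigenvalues

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SIM = ROOT / "scratch" / "simulated"

SEED = 2026
ENSEMBLES = {"free_holoenzyme": 1.0, "regulator_bound": 0.6, "open_complex": 0.3}
DEGREES_PER_UNIT = 1.3
N_PARTICLES = 370_965


def main() -> None:
    OUT.mkdir(exist_ok=True)
    truths = {}
    truth_file = SIM / "ground_truth.json"
    if truth_file.is_file():
        truths = json.loads(truth_file.read_text())

    rows = []
    for i, (label, sigma) in enumerate(ENSEMBLES.items()):
        table = SIM / f"eigen_{label}.txt"
        if table.is_file():
            series = load_eigenvalues(table, component=1)
            theta_bin = truths[f"eigen_{label}.txt"]["theta_bin_deg"]
        else:
            series, truth = simulate_eigenvalues(
                N_PARTICLES, sigma=sigma, degrees_per_unit=DEGREES_PER_UNIT,
                seed=SEED + i,
            )
            theta_bin = truth.parameters["theta_bin_deg"]
        rows.append((label, "opening_closing", series, theta_bin))

    report = clamp_range_report(rows)
    report.to_csv(OUT / "clamp_ranges.csv", index=False)
    print(report.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    r = report.set_index("complex")
    ratio = (r["theta_98_deg"] / r["theta_bin_deg"]).round(4)
    print(f"\ntheta_98 / theta_bin per ensemble: {ratio.to_dict()} "
          "(Gaussian expectation 2.1327)")
    ordered = report["theta_98_deg"].is_monotonic_decreasing
    print("restriction ordering free > bound > open complex:",
          "reproduced" if ordered else "NOT reproduced")


if __name__ == "__main__":
    main()
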