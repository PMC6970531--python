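#!/usr/bin/env python
"""Measure rigid-body domain rotations and the helix kink on known motions.

Applies the geometry pipeline to constructs carrying the motions observed
between RNAP conformational states — the ~121° trigger-loop-insertion (Si3)
flip, the ~18° βlobe-Si1 rotation, the ~4.5° β'shelf rotation, a 1° near-
degenerate case, and bridge-helix kinks of 25° and 29° — and tabulates the
recovered against applied values.  Writes results/domain_motions.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rnapconf.geometry import AxisAngle, domain_rotation, kink_angle
from rnapconf.structio import parse_selection, read_structure
from rnapconf.synthetic import make_kinked_helix, make_two_domain_model

SEED = 2026
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SIM = ROOT / "scratch" / "simulated"

MOTIONS = [
    ("si3_flip", 121.0),
    ("beta_lobe_si1", 18.0),
    ("shelf", 4.5),
    ("near_degenerate", 1.0),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    core, dom = parse_selection("A:1-200"), parse_selection("B:1-188")
    for label, angle in MOTIONS:
        axis = np.array([0.2, -0.6, 0.75])
        ref, moved, _ = make_two_domain_model(
            200, 188, AxisAngle(axis, angle), seed=SEED
        )
        aa = domain_rotation(ref, moved, core, dom)
        rows.append({
            "measurement": f"rotation/{label}",
            "applied_deg": angle,
            "recovered_deg": aa.angle_deg,
            "axis_alignment": float(abs(np.dot(aa.axis, axis / np.linalg.norm(axis)))),
        })

    for angle in (25.0, 29.0):
        helix, _ = make_kinked_helix(40, 20, angle)
        res = kink_angle(helix, parse_selection("A:1-40"), 20)
        rows.append({
            "measurement": f"kink/{angle:g}deg",
            "applied_deg": angle,
            "recovered_deg": res.angle_deg,
            "axis_alignment": np.nan,
        })

    # same measurement off the files written by step 01, if present
    pdb = SIM / "kinked_helix.pdb"
    if pdb.is_file():
        model = read_structure(pdb)
        res = kink_angle(model, parse_selection("A:1-40"), 20)
        rows.append({
            "measurement": "kink/from_pdb_file",
            "applied_deg": 29.0,
            "recovered_deg": res.angle_deg,
            "axis_alignment": np.nan,
        })

    table = pd.DataFrame(rows)
    table["abs_error_deg"] = (table.recovered_deg - table.applied_deg).abs()
    table.to_csv(OUT / "domain_motions.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.6f}"))
    print(f"\nmax |error| = {table.abs_error_deg.max():.2e} deg "
          f"over {len(table)} measurements")


if __name__ == "__main__":
    main()
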