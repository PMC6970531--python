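#!/usr/bin/env python
"""Generate the synthetic inputs used by the downstream analysis steps.

Writes, under results/simulated/: a kinked Cα helix and an 18°-rotated
two-domain model (PDB), per-particle eigenvalue tables for three ensembles
of decreasing clamp mobility, the preset promoter landscapes (JSON), and a
ground-truth sidecar recording every parameter that the later steps try to
recover.
"""

import json
from pathlib import Path

import numpy as np

from rnapconf.geometry import AxisAngle
from rnapconf.structio import write_pdb
from rnapconf.synthetic import (
    make_kinked_helix,
    make_two_domain_model,
    preset_landscapes,
    simulate_eigenvalues,
    write_eigenvalue_table,
)

SEED = 2026
# raw simulated inputs are bulky intermediates; they live under scratch/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"

# Ensembles: clamp-rotation spread (eigenvalue sd) shrinks from the free
# holoenzyme to the regulator-bound enzyme to the promoter-bound open
# complex, at a fixed 1.3 °/unit calibration.
ENSEMBLES = {
    "free_holoenzyme": 1.0,
    "regulator_bound": 0.6,
    "open_complex": 0.3,
}
DEGREES_PER_UNIT = 1.3
N_PARTICLES = 370_965  # matched particle count across ensembles


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truths: dict[str, dict] = {}

    helix, kink_truth = make_kinked_helix(40, 20, 29.0)
    write_pdb(helix, OUT / "kinked_helix.pdb")
    truths["kinked_helix.pdb"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in kink_truth.parameters.items()
    }

    ref, moved, rot_truth = make_two_domain_model(
        200, 188, AxisAngle(np.array([0.2, -0.6, 0.75]), 18.0), seed=SEED
    )
    write_pdb(ref, OUT / "two_domain_ref.pdb")
    write_pdb(moved, OUT / "two_domain_moved.pdb")
    truths["two_domain_moved.pdb"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in rot_truth.parameters.items()
    }

    for i, (label, sigma) in enumerate(ENSEMBLES.items()):
        series, truth = simulate_eigenvalues(
            N_PARTICLES, mu=0.0, sigma=sigma,
            degrees_per_unit=DEGREES_PER_UNIT, seed=SEED + i,
        )
        write_eigenvalue_table(OUT / f"eigen_{label}.txt", series.values,
                               header="component_1")
        truths[f"eigen_{label}.txt"] = truth.parameters

    for name, land in preset_landscapes().items():
        (OUT / f"{name}.json").write_text(json.dumps({
            "state_G": list(land.state_G),
            "barrier_G": list(land.barrier_G),
            "final_barrier_G": land.final_barrier_G,
            "state_names": list(land.state_names),
            "label": land.label,
        }, indent=2) + "\n")
        truths[f"{name}.json"] = {"preset": name}

    (OUT / "ground_truth.json").write_text(json.dumps(truths, indent=2) + "\n")
    print(f"wrote {len(truths)} artifacts to {OUT}")


if __name__ == "__main__":
    main()
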