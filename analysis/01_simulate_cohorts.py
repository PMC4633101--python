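#!/usr/bin/env python
"""Simulate the two study cohorts (6 normal + 6 patient subjects).

Writes S1-layout CSV recordings plus parameter sidecars under
results/recordings/{normal,patient}/.  Later analysis steps read these files,
so the whole chain exercises the same I/O path real recordings would use.
"""

from pathlib import Path

from armdyn.synthetic import SimulationParams, simulate_group
from armdyn.synthetic import save_group

SEED = 0
N_SUBJECTS = 6
OUT = Path(__file__).resolve().parent.parent / "results" / "recordings"


def main() -> None:
    normals = simulate_group(N_SUBJECTS, SimulationParams.normal(seed=SEED), base_seed=SEED)
    patients = simulate_group(
        N_SUBJECTS, SimulationParams.patient(seed=SEED + 1000), base_seed=SEED + 1000
    )
    save_group(normals, OUT / "normal")
    save_group(patients, OUT / "patient")
    print(f"wrote {N_SUBJECTS} normal and {N_SUBJECTS} patient recordings under {OUT}")
    print("each: 2000 samples x 15 channels at 100 Hz (20 s of arm posture)")


if __name__ == "__main__":
    main()
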