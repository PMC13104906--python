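#!/usr/bin/env python
"""Build the synthetic perturbation screen used by the downstream analyses.

Writes a toy screen — vehicle plus four perturbed conditions, one per
architectural axis (trans fraction x2, compartment contrast x1.5, boundary
depletion 1.0 -> 0.2, loop strength x3), four replicates each — as pairs
files with a sample sheet, CpG track, loop list, and ground-truth JSON.

Large pairs files land under scratch/fixture; tables land under results/.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from archscreen.simulate import (
    default_spec,
    make_screen_fixture,
    standard_deltas,
    write_fixture,
)

OUTDIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "fixture")
DEPTH = 150_000
SEED = 20260921


def main():
    deltas = [standard_deltas()[k] for k in
              ("trans_up", "comp_up", "tad_strengthen", "loop_up")]
    spec = default_spec()
    sheet, sets, truth = make_screen_fixture(
        len(deltas), 4, DEPTH, SEED, deltas=deltas, base_spec=spec
    )
    sheet = write_fixture(sheet, sets, truth, spec, OUTDIR)
    spec.loop_bedpe().to_csv(
        os.path.join(OUTDIR, "loops.bedpe"), sep="\t", header=False, index=False
    )
    n_contacts = sum(len(cs) for cs in sets.values())
    print(f"wrote {len(sheet)} samples ({n_contacts:,} contacts) to {OUTDIR}")
    print("conditions:", ", ".join(sheet['condition'].unique()))


if __name__ == "__main__":
    main()
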