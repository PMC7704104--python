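#!/usr/bin/env python
"""Spatial spread of dendritic calcium events: FWHM recovery and labels.

Simulates single-event dendrite movies across a range of injected spatial
widths, runs the ΔF/F → Gaussian-fit pipeline, and tabulates recovered
FWHM and the local/global split at the 50 µm boundary.  Writes
results/fwhm_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fearcalc import imaging, synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-seeds", type=int, default=50)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

rows = []
for fwhm in (10.0, 13.5, 30.0, 81.0):
    length = 60.0 if fwhm < 50 else 200.0
    px = 0.5 if fwhm < 50 else 1.0
    rec, labels = [], []
    for i in range(args.n_seeds):
        truth = synth.DendriteEventTruth(
            events=[synth.DendriteEvent(length / 2, fwhm, 0.8, 5.0)],
            length_um=length, pixel_size_um=px,
        )
        _, traces, _ = synth.simulate_dendrite_movie(truth, seed=args.seed + i)
        dff, _ = imaging.roi_dff_matrix(traces)
        ev = imaging.CalciumEvent("d", 5.0, 5.2, 0.8, 1.0)
        ev = imaging.spatial_fwhm(traces, dff, ev)
        rec.append(ev.fwhm_um)
        labels.append(ev.label)
    rows.append(
        {
            "fwhm_true_um": fwhm,
            "fwhm_recovered_um": np.mean(rec),
            "recovery_error_pct": 100 * (np.mean(rec) - fwhm) / fwhm,
            "sd_um": np.std(rec),
            "pct_global": 100 * labels.count("global") / len(labels),
        }
    )

table = pd.DataFrame(rows)
table.to_csv(args.out_dir / "fwhm_recovery.csv", index=False)
print(table.to_string(index=False))
print("\nEvents near the measured local scale stay local; wide events are "
      "labelled global at the 50 um boundary.")
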