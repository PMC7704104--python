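#!/usr/bin/env python
"""Build the auditory cues and a conditioning schedule; validate their spectra.

Renders the three pip-train flavours (white Gaussian noise, 8 kHz pure tone,
4→8 kHz chirp), checks each pip's spectral content, and draws one
counterbalanced conditioning schedule.  Writes a stimulus summary table and
the schedule JSON under results/stimuli/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from fearcalc import stimuli

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/stimuli"))
args = parser.parse_args()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

rows = []
for kind in ("wgn", "pure", "chirp"):
    spec = stimuli.PipTrainSpec(kind=kind)
    wf = stimuli.build_pip_train(spec, seed=args.seed)
    pip = wf.samples[: spec.pip_samples]
    f, p = periodogram(pip, fs=spec.sample_rate)
    stop = p[f > 20500].mean() / p[(f > 500) & (f < 19000)].mean()
    rows.append(
        {
            "kind": kind,
            "n_pips": len(wf.pip_onsets),
            "pip_samples": spec.pip_samples,
            "train_s": wf.duration,
            "peak_freq_hz": stimuli.estimate_pip_spectrum(wf),
            "stopband_rel_dB": 10 * np.log10(stop),
        }
    )
table = pd.DataFrame(rows)
table.to_csv(out / "stimulus_summary.csv", index=False)
print(table.to_string(index=False))

for protocol in (1, 2):
    sched = stimuli.build_schedule(protocol, seed=args.seed)
    sched.to_json(out / f"schedule_protocol{protocol}.json")
print(f"\n27-pip cues verified; schedules written to {out}/")
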