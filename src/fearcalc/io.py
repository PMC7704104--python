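"""Readers/writers and end-to-end orchestration.

Canonical on-disk units: seconds, mV, µm, dimensionless ΔF/F.  Session time
zero is the recording start; schedules share the same clock.  Supported
formats: CSV for traces/events/scores, JSON for schedules/manifests/sidecar
truth, WAV for waveforms, multi-frame TIFF for movies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ephys import VmTrace
from .imaging import (
    DETECTION_K_SD,
    F0_WINDOW_S,
    GLOBAL_FWHM_UM,
    QC_THRESHOLD,
    CalciumEvent,
    RoiTraceSet,
    compute_dff,
    detect_transients,
    rolling_f0,
)
from .metrics import (
    LEARNER_THRESHOLD_PCT,
    SessionScores,
    classify_learner,
    cumulative_dff,
    learning_correlation,
    learning_index,
    per_cs_counts,
)
from .stimuli import PIP_PERIOD_S, ConditioningSchedule, build_schedule
from .synth import BoutonRateModel, FreezingTruth, simulate_boutons

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_movie",
    "write_movie",
    "read_schedule",
    "write_events",
    "read_events",
    "read_roi_traces",
    "write_roi_traces",
    "read_vm_trace",
]


# ---------------------------------------------------------------------------
# format readers/writers
# ---------------------------------------------------------------------------

def read_movie(path) -> np.ndarray:
    """Multi-frame TIFF → (frames, y, x) array."""
    import tifffile

    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    return np.asarray(movie)


def write_movie(path, movie: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(movie, np.float32))


def read_schedule(path) -> ConditioningSchedule:
    return ConditioningSchedule.from_json(path)


EVENT_COLUMNS = ["roi_id", "onset_s", "peak_s", "amp_dff", "fwhm_um", "label"]


def write_events(path, events: Sequence[CalciumEvent]) -> None:
    rows = [
        {
            "roi_id": e.roi_id,
            "onset_s": e.onset_s,
            "peak_s": e.peak_s,
            "amp_dff": e.amplitude_dff,
            "fwhm_um": e.fwhm_um if e.fwhm_um is not None else np.nan,
            "label": e.label or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[CalciumEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(
            CalciumEvent(
                roi_id=str(r["roi_id"]),
                onset_s=float(r["onset_s"]),
                peak_s=float(r["peak_s"]),
                amplitude_dff=float(r["amp_dff"]),
                template_score=float(r.get("template_score", np.nan)),
                fwhm_um=None if pd.isna(r["fwhm_um"]) else float(r["fwhm_um"]),
                label=None if pd.isna(r["label"]) or r["label"] == "" else str(r["label"]),
            )
        )
    return events


def write_roi_traces(path, traces: RoiTraceSet) -> None:
    """Long-format CSV: time_s, roi_id, value."""
    t = traces.time
    frames = []
    for i, roi in enumerate(traces.roi_ids):
        frames.append(
            pd.DataFrame({"time_s": t, "roi_id": roi, "value": traces.fluorescence[i]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_roi_traces(path, positions_um=None, pixel_size_um=None) -> RoiTraceSet:
    df = pd.read_csv(path)
    rois = list(dict.fromkeys(df["roi_id"]))
    mats, period = [], None
    for roi in rois:
        sub = df[df["roi_id"] == roi]
        t = sub["time_s"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(f"non-monotone time for ROI {roi}")
            period = float(np.median(dt))
        mats.append(sub["value"].to_numpy(float))
    return RoiTraceSet(
        fluorescence=np.vstack(mats),
        frame_period=period or 1.0,
        positions_um=positions_um,
        pixel_size_um=pixel_size_um,
        roi_ids=rois,
    )


def read_vm_trace(path, stim_onset: float, stim_offset: float,
                  condition: str = "control") -> VmTrace:
    """CSV with columns time_s, vm_mV (uniform sampling required)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6 * np.median(dt) + 1e-9):
        raise ValueError("time base must be uniform and increasing")
    rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    return VmTrace(vm=df["vm_mV"].to_numpy(float), sample_rate=rate,
                   stim_onset=stim_onset, stim_offset=stim_offset,
                   condition=condition)


# ---------------------------------------------------------------------------
# end-to-end synthetic session pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one synthetic cohort run.

    Threshold defaults are the analysis constants (k=3 SD, 50 µm, 3 s F0
    window, 0.7 frame QC, 20% learner threshold); overrides are recorded in
    the output manifest.
    """

    seed: int = 0
    out_dir: str = "results/pipeline"
    n_animals: int = 10
    n_learners: int = 5
    bin_s: float = PIP_PERIOD_S
    k_sd: float = DETECTION_K_SD
    fwhm_threshold_um: float = GLOBAL_FWHM_UM
    f0_window_s: float = F0_WINDOW_S
    qc_threshold: float = QC_THRESHOLD
    learner_threshold: float = LEARNER_THRESHOLD_PCT
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def detect_bouton_events(
    traces: RoiTraceSet, k: float = DETECTION_K_SD, f0_window_s: float = F0_WINDOW_S
) -> list[CalciumEvent]:
    """Rolling-F0 → ΔF/F → template detection over every bouton trace."""
    events: list[CalciumEvent] = []
    for i, roi in enumerate(traces.roi_ids):
        f = traces.fluorescence[i]
        f0, warmup = rolling_f0(f, traces.frame_period, window_s=f0_window_s)
        dff = compute_dff(f, f0, traces.frame_period, warmup, roi_id=roi)
        events.extend(detect_transients(dff, k=k, roi_id=roi,
                                        qc_mask=traces.qc_mask))
    return events


def score_animal(
    animal_id: str,
    events: Sequence[CalciumEvent],
    schedule: ConditioningSchedule,
    freezing_cs_plus: float,
    freezing_cs_minus: float,
    learner_threshold: float = LEARNER_THRESHOLD_PCT,
    n_rois: int | None = None,
) -> SessionScores:
    """Assemble the per-animal score record from detected events + freezing."""
    counts = per_cs_counts(events, schedule)
    per_epoch, mean_plus, mean_minus, delta = cumulative_dff(events, schedule, n_rois)
    idx = learning_index(freezing_cs_plus, freezing_cs_plus, freezing_cs_minus)
    return SessionScores(
        animal_id=animal_id,
        freezing_cs_plus=freezing_cs_plus,
        freezing_cs_minus=freezing_cs_minus,
        learning_index=idx,
        learner=classify_learner(idx, learner_threshold),
        per_cs_counts=counts.to_dict(orient="list"),
        cumulative_dff={f"{k[0]}{k[1]}": v for k, v in per_epoch.items()},
        mean_cumulative_cs_plus=mean_plus,
        mean_cumulative_cs_minus=mean_minus,
        delta_cumulative=delta,
    )


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Synthetic cohort end-to-end: stimuli → boutons → detection → scores.

    For each animal a conditioning schedule is drawn, axonal bouton traces
    are simulated (learner or non-learner profile), transients are detected,
    per-CS statistics computed, and recall freezing generated from the
    animal's measured Δcumulative through the cohort relation.  Writes
    ``scores.csv``, ``cohort.json`` and ``manifest.json`` under
    ``config.out_dir`` and returns the score table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freezing_truth = FreezingTruth()
    rows = []
    for i in range(config.n_animals):
        a_seed = (config.seed * 1009 + 7 * i + 1) % (2**31)
        protocol = 1 if i % 2 == 0 else 2
        schedule = build_schedule(protocol, seed=a_seed)
        learner = i < config.n_learners
        model = BoutonRateModel() if learner else BoutonRateModel.non_learner()
        traces, _truth = simulate_boutons(model, schedule, seed=a_seed + 1)
        events = detect_bouton_events(traces, k=config.k_sd,
                                      f0_window_s=config.f0_window_s)
        _, mean_plus, mean_minus, delta = cumulative_dff(events, schedule,
                                                         traces.n_rois)
        rng = np.random.default_rng(a_seed + 2)
        f_plus = float(np.clip(
            freezing_truth.slope * delta + freezing_truth.intercept
            + rng.normal(0, freezing_truth.noise_sd), 0, 100))
        f_minus = float(rng.uniform(5.0, 20.0))
        scores = score_animal(f"mouse{i:02d}", events, schedule, f_plus, f_minus,
                              config.learner_threshold, n_rois=traces.n_rois)
        rows.append(
            {
                "animal_id": scores.animal_id,
                "protocol": protocol,
                "simulated_learner": learner,
                "n_events": len(events),
                "mean_cumulative_cs_plus": scores.mean_cumulative_cs_plus,
                "mean_cumulative_cs_minus": scores.mean_cumulative_cs_minus,
                "delta_cumulative": scores.delta_cumulative,
                "freezing_cs_plus": scores.freezing_cs_plus,
                "freezing_cs_minus": scores.freezing_cs_minus,
                "learning_index": scores.learning_index,
                "learner": scores.learner,
            }
        )
    table = pd.DataFrame(rows)

    cohort = table.rename(columns={"freezing_cs_plus": "freezing_pct"})[
        ["delta_cumulative", "freezing_pct"]
    ]
    slope, intercept, r2 = learning_correlation(cohort)
    table.to_csv(out / "scores.csv", index=False)
    with open(out / "cohort.json", "w") as fh:
        json.dump(
            {"slope": slope, "intercept": intercept, "r_squared": r2,
             "n_animals": config.n_animals},
            fh, indent=2,
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"fearcalc_version": __version__, "config": asdict(config)},
            fh, indent=2,
        )
    return table
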