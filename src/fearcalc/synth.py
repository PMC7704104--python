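"""Synthetic ground-truth generators for every input class of the pipeline.

Each generator is a pure function of ``(truth, seed)`` and returns the
simulated data together with a sidecar dictionary of the injected ground
truth, so every downstream stage can be tested closed-loop:

* :func:`simulate_vm` — two-state (up/down) telegraph membrane potential
  with Gaussian noise, optional stereotyped spikes, and a sustained evoked
  depolarisation step that persists at least 30 s beyond the stimulation;
* :func:`simulate_dendrite_movie` — a dendrite imaged as a 2-pixel-wide
  strip; each calcium event has a Gaussian spatial footprint of known FWHM
  and a double-exponential time course, with shot-noise-like pixel noise;
* :func:`simulate_boutons` — axonal bouton ΔF/F traces driven by an
  inhomogeneous Poisson process whose per-epoch rates follow the measured
  per-CS transient counts of conditioned animals (learner and non-learner
  profiles);
* :func:`simulate_cohort` — per-animal (Δcumulative, recall freezing)
  pairs from a linear relation with configurable noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ephys import VmTrace
from .imaging import RoiTraceSet, double_exp_kernel
from .stimuli import CS_MINUS, CS_PLUS, ConditioningSchedule

__all__ = [
    "VmGroundTruth",
    "DendriteEvent",
    "DendriteEventTruth",
    "BoutonRateModel",
    "FreezingTruth",
    "simulate_vm",
    "simulate_dendrite_movie",
    "simulate_boutons",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# membrane potential
# ---------------------------------------------------------------------------

@dataclass
class VmGroundTruth:
    """Parameters of the two-state Vm simulation (mV, s, Hz)."""

    up_state_mV: float = -63.5
    down_state_mV: float = -68.5
    up_dwell_s: float = 0.15
    down_dwell_s: float = 0.25
    evoked_step_mV: float = 1.0  # sustained depolarisation during/after stim
    nmdar_fraction: float = 1.0  # share of the step removed by a blocker
    spike_rate: float = 0.3  # Hz
    noise_sd: float = 0.8  # mV
    sample_rate: float = 1000.0

    def validate(self) -> None:
        if self.up_state_mV <= self.down_state_mV:
            raise ValueError("up state must be depolarised relative to down state")
        if not (0.0 <= self.nmdar_fraction <= 1.0):
            raise ValueError("nmdar_fraction must lie in [0, 1]")


def simulate_vm(
    truth: VmGroundTruth,
    stim_onset: float,
    stim_offset: float,
    duration: float,
    seed: int = 0,
    blocker: bool = False,
    condition: str | None = None,
) -> tuple[VmTrace, dict]:
    """Telegraph Vm + noise + spikes + evoked step; deterministic per seed.

    The evoked step is ``evoked_step_mV`` (scaled by ``1 - nmdar_fraction``
    when ``blocker`` simulates NMDAR blockade) added from stimulation onset
    until the end of the trace, i.e. persisting beyond 30 s post-offset.
    Spikes are 2 ms triangular excursions to +30 mV.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration * truth.sample_rate))
    dt = 1.0 / truth.sample_rate

    # alternating exponential dwells; a 10 s burn-in puts the process in its
    # stationary regime before the trace starts
    burn = int(round(10.0 * truth.sample_rate))
    p_up = truth.up_dwell_s / (truth.up_dwell_s + truth.down_dwell_s)
    state_up = rng.random() < p_up
    vm = np.empty(n + burn)
    i = 0
    while i < n + burn:
        dwell = rng.exponential(truth.up_dwell_s if state_up else truth.down_dwell_s)
        j = min(n + burn, i + max(1, int(round(dwell / dt))))
        vm[i:j] = truth.up_state_mV if state_up else truth.down_state_mV
        state_up = not state_up
        i = j
    vm = vm[burn:]

    vm += rng.normal(0.0, truth.noise_sd, n)

    step = truth.evoked_step_mV * ((1.0 - truth.nmdar_fraction) if blocker else 1.0)
    i_on = int(round(stim_onset * truth.sample_rate))
    vm[i_on:] += step

    n_spikes = rng.poisson(truth.spike_rate * duration)
    spike_half = max(1, int(round(0.001 * truth.sample_rate)))  # 1 ms rise, 1 ms fall
    ramp = np.linspace(0.0, 1.0, spike_half + 1)
    shape = np.concatenate([ramp, ramp[-2::-1]])
    for t_spk in rng.uniform(0, duration, n_spikes):
        c = int(round(t_spk * truth.sample_rate))
        lo = max(0, c - spike_half)
        hi = min(n, c + spike_half + 1)
        seg = shape[lo - (c - spike_half) : len(shape) - ((c + spike_half + 1) - hi)]
        vm[lo:hi] = np.maximum(vm[lo:hi], 30.0 * seg + (1 - seg) * vm[lo:hi])

    trace = VmTrace(
        vm=vm,
        sample_rate=truth.sample_rate,
        stim_onset=stim_onset,
        stim_offset=stim_offset,
        condition=condition or ("blocked" if blocker else "control"),
    )
    sidecar = dict(asdict(truth), seed=seed, blocker=blocker,
                   applied_step_mV=step, n_spikes=int(n_spikes))
    return trace, sidecar


# ---------------------------------------------------------------------------
# dendrite movies
# ---------------------------------------------------------------------------

@dataclass
class DendriteEvent:
    center_um: float
    fwhm_um: float
    amplitude_dff: float
    onset_s: float
    rise_s: float = 0.18  # slow-indicator kinetics for dendrites
    decay_s: float = 1.2


@dataclass
class DendriteEventTruth:
    """A dendrite, its events, and the imaging geometry/noise."""

    events: list[DendriteEvent] = field(default_factory=list)
    length_um: float = 60.0
    pixel_size_um: float = 0.5
    frame_period_s: float = 0.032
    duration_s: float = 12.0
    baseline_f: float = 100.0
    noise_sd: float = 12.0  # pixel fluorescence units at baseline brightness

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        for e in self.events:
            if e.fwhm_um <= 0:
                raise ValueError("event FWHM must be > 0")
            if not (0.0 <= e.center_um <= self.length_um):
                raise ValueError("event centre must lie on the dendrite")
            if not (e.decay_s > e.rise_s > 0):
                raise ValueError("need decay > rise > 0")


def simulate_dendrite_movie(
    truth: DendriteEventTruth, seed: int = 0
) -> tuple[np.ndarray, RoiTraceSet, dict]:
    """Render a (frames × 2 × pixels) strip movie plus 2×2-px ROI traces.

    Each event contributes ``amp · exp(-(x-c)²/2σ²)`` spatially, with
    ``σ = fwhm / (2√(2 ln 2))``, times a unit-peak double-exponential time
    course.  Pixel noise is Gaussian with sd scaling as √F (shot-noise-like).
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    n_px = int(round(truth.length_um / truth.pixel_size_um))
    n_frames = int(round(truth.duration_s / truth.frame_period_s))
    x = (np.arange(n_px) + 0.5) * truth.pixel_size_um
    t = np.arange(n_frames) * truth.frame_period_s

    dff = np.zeros((n_frames, n_px))
    for e in truth.events:
        sigma = e.fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        spatial = np.exp(-((x - e.center_um) ** 2) / (2 * sigma**2))
        kernel = double_exp_kernel(e.rise_s, e.decay_s, truth.frame_period_s)
        temporal = np.zeros(n_frames)
        i0 = int(round(e.onset_s / truth.frame_period_s))
        j = min(n_frames, i0 + len(kernel))
        if j > i0 >= 0:
            temporal[i0:j] = kernel[: j - i0]
        dff += e.amplitude_dff * np.outer(temporal, spatial)

    f = truth.baseline_f * (1.0 + dff)
    movie = np.repeat(f[:, None, :], 2, axis=1)
    movie += rng.normal(0.0, 1.0, movie.shape) * truth.noise_sd * np.sqrt(
        np.clip(movie, 0, None) / truth.baseline_f
    )

    # 2x2-pixel ROI tiles along the dendrite
    n_tiles = n_px // 2
    tiles = movie[:, :, : 2 * n_tiles].reshape(n_frames, 2, n_tiles, 2)
    roi_f = tiles.mean(axis=(1, 3)).T  # (n_rois, n_frames)
    positions = (2 * np.arange(n_tiles) + 1.0) * truth.pixel_size_um
    traces = RoiTraceSet(
        fluorescence=roi_f,
        frame_period=truth.frame_period_s,
        positions_um=positions,
        pixel_size_um=truth.pixel_size_um,
    )
    sidecar = {
        "seed": seed,
        "length_um": truth.length_um,
        "events": [asdict(e) for e in truth.events],
        "noise_sd": truth.noise_sd,
    }
    return movie, traces, sidecar


# ---------------------------------------------------------------------------
# axonal boutons
# ---------------------------------------------------------------------------

@dataclass
class BoutonRateModel:
    """Per-epoch transient rates (Hz) of amygdalar axonal boutons.

    Default rates convert the per-CS transient counts measured in
    conditioned animals (counts per 30 s CS) into Hz.  The learner profile
    keeps the first CS+ — monitored before any footshock — near baseline
    and raises subsequent paired CS+ and all CS−; the non-learner profile
    is flat across epochs.
    """

    learner: bool = True
    n_boutons: int = 20
    baseline_hz: float = 0.02
    cs_plus_first_hz: float = 1.03 / 30.0
    cs_plus_paired_hz: float = 1.97 / 30.0
    cs_minus_hz: float = 2.07 / 30.0
    amp_log_mean: float = float(np.log(0.3))  # lognormal peak ΔF/F
    amp_log_sd: float = 0.35
    rise_s: float = 0.05  # fast-indicator kinetics for axons
    decay_s: float = 0.4
    frame_period_s: float = 0.256
    baseline_f: float = 100.0
    noise_dff_sd: float = 0.05

    @classmethod
    def non_learner(cls, **kw) -> "BoutonRateModel":
        return cls(
            learner=False,
            cs_plus_first_hz=0.74 / 30.0,
            cs_plus_paired_hz=0.68 / 30.0,
            cs_minus_hz=0.77 / 30.0,
            **kw,
        )

    def validate(self) -> None:
        for r in (self.baseline_hz, self.cs_plus_first_hz,
                  self.cs_plus_paired_hz, self.cs_minus_hz):
            if r < 0:
                raise ValueError("rates must be >= 0")

    def rate_for(self, label: str, epoch_index: int) -> float:
        if label == CS_PLUS:
            return self.cs_plus_first_hz if epoch_index == 1 else self.cs_plus_paired_hz
        if label == CS_MINUS:
            return self.cs_minus_hz
        return self.baseline_hz  # baseline, US gaps, inter-trial intervals


def simulate_boutons(
    model: BoutonRateModel,
    schedule: ConditioningSchedule,
    seed: int = 0,
) -> tuple[RoiTraceSet, dict]:
    """Inhomogeneous-Poisson bouton event trains rendered as ΔF/F traces.

    Event times are drawn per bouton with the model's per-epoch rates,
    amplitudes are lognormal, and each event is convolved with the fast
    indicator kernel on a baseline of ``baseline_f`` fluorescence units with
    additive Gaussian noise of ``noise_dff_sd`` (ΔF/F units).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    duration = schedule.duration
    n_frames = int(round(duration / model.frame_period_s))
    t_frames = np.arange(n_frames) * model.frame_period_s
    kernel = double_exp_kernel(model.rise_s, model.decay_s, model.frame_period_s)

    # piecewise-constant rate segments covering the whole session
    cs_index = {CS_PLUS: 0, CS_MINUS: 0}
    segments: list[tuple[float, float, float]] = []
    cursor = 0.0
    for epoch in sorted(schedule.epochs, key=lambda e: e.onset):
        if epoch.onset > cursor:
            segments.append((cursor, epoch.onset, model.baseline_hz))
        if epoch.label in cs_index:
            cs_index[epoch.label] += 1
            rate = model.rate_for(epoch.label, cs_index[epoch.label])
        else:
            rate = model.rate_for(epoch.label, 0)
        segments.append((epoch.onset, epoch.offset, rate))
        cursor = epoch.offset
    if cursor < duration:
        segments.append((cursor, duration, model.baseline_hz))

    fl = np.empty((model.n_boutons, n_frames))
    truth_events = []
    for b in range(model.n_boutons):
        times = []
        for t0, t1, rate in segments:
            k = rng.poisson(rate * (t1 - t0))
            times.extend(rng.uniform(t0, t1, k))
        times = np.sort(times)
        amps = rng.lognormal(model.amp_log_mean, model.amp_log_sd, len(times))
        dff = np.zeros(n_frames)
        for t_ev, a in zip(times, amps):
            i0 = int(np.ceil(t_ev / model.frame_period_s))
            j = min(n_frames, i0 + len(kernel))
            if j > i0 >= 0:
                dff[i0:j] += a * kernel[: j - i0]
        dff += rng.normal(0.0, model.noise_dff_sd, n_frames)
        fl[b] = model.baseline_f * (1.0 + dff)
        truth_events.append(
            {"roi_id": f"bouton{b:03d}", "times_s": [float(x) for x in times],
             "amplitudes_dff": [float(a) for a in amps]}
        )

    traces = RoiTraceSet(
        fluorescence=fl,
        frame_period=model.frame_period_s,
        roi_ids=[f"bouton{b:03d}" for b in range(model.n_boutons)],
    )
    sidecar = {"seed": seed, "learner": model.learner, "events": truth_events,
               "rates_hz": {"baseline": model.baseline_hz,
                            "cs_plus_first": model.cs_plus_first_hz,
                            "cs_plus_paired": model.cs_plus_paired_hz,
                            "cs_minus": model.cs_minus_hz}}
    return traces, sidecar


# ---------------------------------------------------------------------------
# behavioural cohort
# ---------------------------------------------------------------------------

@dataclass
class FreezingTruth:
    """Linear Δcumulative → recall-freezing relation for a cohort.

    The default slope/intercept map the observed Δcumulative range
    (roughly 0–0.12 ΔF/F) onto recall freezing between ~15% and ~75%;
    the 6% freezing noise reproduces the strength of the reported cohort
    relation (r² ≈ 0.89) over that range.
    """

    slope: float = 500.0  # % freezing per unit Δcumulative
    intercept: float = 15.0  # %
    noise_sd: float = 6.0  # %
    delta_range: tuple[float, float] = (0.0, 0.12)
    habituation_freezing_max: float = 15.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def simulate_cohort(
    truth: FreezingTruth, n_animals: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Per-animal (Δcumulative, freezing %) table; freezing clipped to [0, 100]."""
    truth.validate()
    if n_animals < 3:
        raise ValueError("need at least 3 animals")
    rng = np.random.default_rng(seed)
    delta = rng.uniform(*truth.delta_range, n_animals)
    noise = rng.normal(0.0, truth.noise_sd, n_animals) if truth.noise_sd > 0 else 0.0
    freezing = np.clip(truth.slope * delta + truth.intercept + noise, 0.0, 100.0)
    hab = rng.uniform(0.0, truth.habituation_freezing_max, n_animals)
    return pd.DataFrame(
        {
            "animal_id": [f"mouse{i:02d}" for i in range(n_animals)],
            "delta_cumulative": delta,
            "freezing_pct": freezing,
            "habituation_freezing_pct": hab,
        }
    )
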