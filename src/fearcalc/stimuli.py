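"""Auditory pip-train stimuli and differential fear-conditioning schedules.

The behavioural protocol delivers 30 s auditory cues built from short (50 ms)
pips repeated at 0.9 Hz — 27 pips per cue.  Three pip flavours are supported:
white Gaussian noise (WGN; random Gaussian samples, low-pass filtered at
20 kHz to avoid aliasing and ultrasonic content), pure sinusoidal tones, and
linear chirps.  Conditioning interleaves five CS+ presentations, each
terminated by a 1 s footshock (US) whose onset coincides with the CS+ offset,
with five CS− presentations, separated by variable 10–60 s inter-stimulus
intervals.  Tone identity (8 kHz vs WGN) is counterbalanced across the two
protocol variants.

Waveforms carry no absolute sound-pressure calibration: pips are unit-RMS
normalised and the nominal level (80 dB SPL) is kept as metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal

__all__ = [
    "PipTrainSpec",
    "StimulusWaveform",
    "Epoch",
    "ConditioningSchedule",
    "build_pip_train",
    "estimate_pip_spectrum",
    "build_schedule",
]

#: pip period implied by the 0.9 Hz repetition rate, seconds
PIP_PERIOD_S = 1.0 / 0.9


@dataclass(frozen=True)
class PipTrainSpec:
    """Parameters of one pip-train auditory cue.

    Defaults reproduce the conditioning cues: 27 pips of 50 ms at 0.9 Hz over
    30 s, sampled at 44100 Hz and low-passed at 20 kHz.
    """

    kind: Literal["wgn", "pure", "chirp"] = "wgn"
    pip_duration: float = 0.050
    rate: float = 0.9
    train_duration: float = 30.0
    sample_rate: float = 44100.0
    tone_freq: float = 8000.0
    chirp_f0: float = 4000.0
    chirp_f1: float = 8000.0
    lowpass_cutoff: float = 20000.0
    level_dB: float = 80.0  # metadata only; samples are unit-RMS

    @property
    def pip_samples(self) -> int:
        n = self.pip_duration * self.sample_rate
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9 or n_int <= 0 and self.train_duration > 0:
            raise ValueError(
                f"pip_duration*sample_rate must be a positive integer, got {n}"
            )
        return n_int

    @property
    def n_pips(self) -> int:
        return int(np.floor(self.rate * self.train_duration + 1e-9))

    def validate(self) -> None:
        if self.kind not in ("wgn", "pure", "chirp"):
            raise ValueError(f"unknown pip kind {self.kind!r}")
        if self.train_duration < 0:
            raise ValueError("train_duration must be >= 0")
        if self.lowpass_cutoff >= self.sample_rate / 2:
            raise ValueError("lowpass_cutoff must be below the Nyquist frequency")
        if self.train_duration > 0:
            self.pip_samples  # raises on non-integer pip sample count


@dataclass
class StimulusWaveform:
    """A rendered pip train: dimensionless samples plus pip onset times."""

    samples: np.ndarray
    sample_rate: float
    pip_onsets: np.ndarray  # seconds
    spec: PipTrainSpec | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_wav(self, path) -> None:
        """Write as 16-bit PCM WAV (peak-normalised to 0.9 full scale)."""
        from scipy.io import wavfile

        x = np.asarray(self.samples, dtype=float)
        peak = np.max(np.abs(x)) if len(x) else 0.0
        if peak > 0:
            x = x / peak * 0.9
        wavfile.write(path, int(self.sample_rate), (x * 32767).astype(np.int16))

    def to_csv(self, path) -> None:
        t = np.arange(len(self.samples)) / self.sample_rate
        np.savetxt(
            path,
            np.column_stack([t, self.samples]),
            delimiter=",",
            header="time_s,amplitude",
            comments="",
        )


def _lowpass(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    # Zero-phase FIR; 257 Hamming-window taps give > 40 dB stopband attenuation
    # per pass (doubled by filtfilt).
    numtaps = 257
    if len(x) <= 3 * numtaps:
        numtaps = max(5, (len(x) // 3) | 1)
    b = signal.firwin(numtaps, cutoff, fs=fs)
    return signal.filtfilt(b, [1.0], x)


def _render_pip(spec: PipTrainSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.pip_samples
    t = np.arange(n) / spec.sample_rate
    if spec.kind == "wgn":
        pip = rng.standard_normal(n)
        pip = _lowpass(pip, spec.lowpass_cutoff, spec.sample_rate)
    elif spec.kind == "pure":
        pip = np.sin(2 * np.pi * spec.tone_freq * t)
    else:  # chirp: swept-frequency cosine
        pip = signal.chirp(t, f0=spec.chirp_f0, t1=spec.pip_duration, f1=spec.chirp_f1)
    rms = np.sqrt(np.mean(pip**2))
    if rms > 0:
        pip = pip / rms
    return pip


def build_pip_train(spec: PipTrainSpec, seed: int = 0) -> StimulusWaveform:
    """Render a pip train deterministically from ``(spec, seed)``.

    Pips are placed at exact multiples of the pip period starting at t = 0.
    WGN pips are fresh Gaussian draws per pip; tonal pips are identical.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_total = int(round(spec.train_duration * spec.sample_rate))
    samples = np.zeros(n_total)
    onsets = np.arange(spec.n_pips) / spec.rate
    for onset in onsets:
        i0 = int(round(onset * spec.sample_rate))
        pip = _render_pip(spec, rng)
        i1 = min(i0 + len(pip), n_total)
        samples[i0:i1] = pip[: i1 - i0]
    return StimulusWaveform(samples=samples, sample_rate=spec.sample_rate,
                            pip_onsets=onsets, spec=spec)


def estimate_pip_spectrum(waveform: StimulusWaveform) -> float:
    """Dominant frequency (Hz) of the first pip, from the discrete spectrum.

    A validation helper for generated tones: pure pips peak at their carrier,
    chirps inside their sweep band; WGN has no meaningful single peak.
    """
    if len(waveform.pip_onsets) == 0:
        raise ValueError("waveform contains no pips")
    spec = waveform.spec
    n_pip = (
        spec.pip_samples
        if spec is not None
        else int(round((waveform.pip_onsets[1:2].tolist() or [0.05])[0] * waveform.sample_rate))
    )
    i0 = int(round(waveform.pip_onsets[0] * waveform.sample_rate))
    pip = waveform.samples[i0 : i0 + n_pip]
    if len(pip) == 0:
        raise ValueError("empty pip segment")
    spectrum = np.abs(np.fft.rfft(pip))
    freqs = np.fft.rfftfreq(len(pip), d=1.0 / waveform.sample_rate)
    return float(freqs[np.argmax(spectrum)])


# ---------------------------------------------------------------------------
# Conditioning schedules
# ---------------------------------------------------------------------------

CS_PLUS = "CS+"
CS_MINUS = "CS-"
US = "US"
BASELINE = "baseline"

#: tone assignment per protocol variant (counterbalanced across animals)
PROTOCOL_TONES = {
    1: {CS_PLUS: "pure_8khz", CS_MINUS: "wgn"},
    2: {CS_PLUS: "wgn", CS_MINUS: "pure_8khz"},
}


@dataclass(frozen=True)
class Epoch:
    label: str
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class ConditioningSchedule:
    """Ordered CS+/CS−/US epochs of one differential-conditioning session."""

    epochs: list[Epoch]
    protocol: int
    tone_assignment: dict[str, str]
    seed: int

    def by_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    @property
    def cs_plus(self) -> list[Epoch]:
        return self.by_label(CS_PLUS)

    @property
    def cs_minus(self) -> list[Epoch]:
        return self.by_label(CS_MINUS)

    @property
    def us(self) -> list[Epoch]:
        return self.by_label(US)

    @property
    def duration(self) -> float:
        return max(e.offset for e in self.epochs)

    def validate(self, require_cs_minus: bool = True) -> None:
        if len(self.cs_plus) != 5:
            raise ValueError(f"expected 5 CS+ epochs, found {len(self.cs_plus)}")
        if require_cs_minus and len(self.cs_minus) != 5:
            raise ValueError(f"expected 5 CS- epochs, found {len(self.cs_minus)}")
        if len(self.us) != len(self.cs_plus):
            raise ValueError("every CS+ must be paired with a US")
        cs_offsets = [e.offset for e in self.cs_plus]
        for us in self.us:
            if not any(abs(us.onset - off) < 1e-9 for off in cs_offsets):
                raise ValueError("US onset must coincide with a CS+ offset")
            if abs(us.duration - 1.0) > 1e-9:
                raise ValueError("US duration must be 1 s")
        # non-overlap except US abutting CS+
        ordered = sorted(self.epochs, key=lambda e: e.onset)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(f"overlapping epochs: {a} / {b}")

    def to_json(self, path=None) -> str:
        payload = {
            "protocol": self.protocol,
            "seed": self.seed,
            "tone_assignment": self.tone_assignment,
            "epochs": [
                {"label": e.label, "onset_s": e.onset, "offset_s": e.offset}
                for e in self.epochs
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ConditioningSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        epochs = [
            Epoch(e["label"], float(e["onset_s"]), float(e["offset_s"]))
            for e in payload["epochs"]
        ]
        sched = cls(
            epochs=epochs,
            protocol=int(payload["protocol"]),
            tone_assignment=dict(payload["tone_assignment"]),
            seed=int(payload.get("seed", 0)),
        )
        sched.validate(require_cs_minus=any(e.label == CS_MINUS for e in epochs))
        return sched


def build_schedule(
    protocol: int,
    seed: int = 0,
    n_pairings: int = 5,
    baseline_s: float = 30.0,
    cs_duration: float = 30.0,
    us_duration: float = 1.0,
    isi_range: tuple[float, float] = (10.0, 60.0),
    include_cs_minus: bool = True,
) -> ConditioningSchedule:
    """Draw one conditioning session deterministically from ``(protocol, seed)``.

    CS+ and CS− strictly alternate (CS+ first; every CS+ offset abuts a 1 s
    US).  Only the gaps between the end of one epoch group and the onset of
    the next are random, uniform in ``isi_range``.  ``include_cs_minus=False``
    builds the no-CS− control variant.
    """
    if protocol not in PROTOCOL_TONES:
        raise ValueError(f"unknown protocol id {protocol!r}")
    rng = np.random.default_rng(seed)
    epochs: list[Epoch] = [Epoch(BASELINE, 0.0, baseline_s)]
    t = baseline_s
    for i in range(n_pairings):
        epochs.append(Epoch(CS_PLUS, t, t + cs_duration))
        t += cs_duration
        epochs.append(Epoch(US, t, t + us_duration))
        t += us_duration
        t += float(rng.uniform(*isi_range))
        if include_cs_minus:
            epochs.append(Epoch(CS_MINUS, t, t + cs_duration))
            t += cs_duration
            if i < n_pairings - 1:
                t += float(rng.uniform(*isi_range))
        # without CS-, the post-US ISI directly precedes the next CS+
    sched = ConditioningSchedule(
        epochs=epochs,
        protocol=protocol,
        tone_assignment=dict(PROTOCOL_TONES[protocol]),
        seed=seed,
    )
    sched.validate(require_cs_minus=include_cs_minus)
    return sched
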