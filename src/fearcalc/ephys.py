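"""Cumulative membrane-potential (cVm) analysis.

Whole-cell Vm under anaesthesia fluctuates spontaneously between up and down
states, which makes single-trial evoked depolarisation hard to read off the
raw trace.  The cVm-change statistic integrates it out: Vm is averaged in
bins locked to the stimulus clock (one pip period, 1/0.9 s, by default), a
baseline ordinary-least-squares trend is removed, and the residual bin means
are cumulated.  The curve is summarised at two time points: t1, the end of
the 30 s stimulation, and t2, 30 s later.  For a sustained depolarisation of
``s`` mV over the 27-bin stimulation the value at t1 is exactly ``27*s`` mV.

The baseline trend is estimated on the per-bin mean Vm (slope + intercept)
and subtracted before cumulating.  With a stationary baseline this is
equivalent, in expectation, to subtracting the extrapolated linear
regression of the cumulative curve itself, but it additionally cancels a
linear instrumental drift in Vm exactly — the statistic is invariant to any
affine trend ``a + b*t`` added to the whole trace.

Spikes are not modelled: suprathreshold excursions are interpolated away
before cumulating so the statistic reflects subthreshold depolarisation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .stimuli import PIP_PERIOD_S

__all__ = [
    "VmTrace",
    "CvmCurve",
    "remove_spikes",
    "cvm_change",
    "nmdar_component",
    "supralinearity",
]

#: interval between the two analysis time points (t2 = t1 + 30 s)
T2_DELAY_S = 30.0


@dataclass
class VmTrace:
    """Uniformly sampled membrane potential with a stimulation annotation."""

    vm: np.ndarray  # mV
    sample_rate: float  # Hz
    stim_onset: float  # s
    stim_offset: float  # s
    condition: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vm = np.asarray(self.vm, dtype=float)
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("Vm contains non-finite samples")
        if not (0 <= self.stim_onset < self.stim_offset <= self.duration + 1e-9):
            raise ValueError("stimulation window must lie within the trace")

    @property
    def duration(self) -> float:
        return len(self.vm) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.vm)) / self.sample_rate


@dataclass
class CvmCurve:
    """Baseline-detrended cumulative Vm, with values at t1 and t2 (mV)."""

    time: np.ndarray  # right edge of each bin, s
    cvm: np.ndarray  # mV
    bin_s: float
    baseline_window: tuple[float, float]
    t1: float
    t2: float | None
    value_t1: float
    value_t2: float | None
    condition: str = "control"


def remove_spikes(trace: VmTrace, threshold_mV: float = -20.0) -> VmTrace:
    """Replace suprathreshold samples by linear interpolation.

    Samples above ``threshold_mV`` are removed and bridged linearly between
    the flanking subthreshold samples; at the trace edges the nearest valid
    sample is held.  The number of replaced samples is recorded in
    ``meta["spike_samples"]``.
    """
    vm = trace.vm
    above = vm > threshold_mV
    if above.all():
        raise ValueError("entire trace above spike threshold")
    if not above.any():
        out = replace(trace, vm=vm.copy())
        out.meta = dict(trace.meta, spike_samples=0)
        return out
    idx = np.arange(len(vm))
    clean = np.interp(idx, idx[~above], vm[~above])
    out = replace(trace, vm=clean)
    out.meta = dict(trace.meta, spike_samples=int(above.sum()))
    return out


def cvm_change(
    trace: VmTrace,
    bin_s: float = PIP_PERIOD_S,
    baseline_window: tuple[float, float] | None = None,
) -> CvmCurve:
    """Cumulative depolarisation relative to the baseline trend.

    Parameters
    ----------
    trace:
        Spike-free Vm trace (run :func:`remove_spikes` first if needed).
    bin_s:
        Bin width of the cumulative sum; defaults to one pip period so the
        30 s stimulation spans exactly 27 bins.
    baseline_window:
        ``(start, end)`` of the baseline, ending at stimulation onset.
        Defaults to ``(0, stim_onset)``.
    """
    if baseline_window is None:
        baseline_window = (0.0, trace.stim_onset)
    b0, b1 = baseline_window
    if abs(b1 - trace.stim_onset) > 1e-6:
        raise ValueError("baseline window must end at stimulation onset")
    n_bins = int(np.floor(trace.duration / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    samples_per_bin = trace.sample_rate * bin_s
    edges = (np.arange(n_bins + 1) * samples_per_bin).round().astype(int)
    binned = np.add.reduceat(trace.vm[: edges[-1]], edges[:-1]) / np.diff(edges)
    # abscissa = mean sample time per bin (edges are rounded to whole
    # samples, so nominal bin centres would leave a drift residual)
    centers = (edges[:-1] + edges[1:] - 1) / 2.0 / trace.sample_rate
    right = (np.arange(n_bins) + 1.0) * bin_s

    in_baseline = (centers > b0) & (right <= b1 + 1e-9)
    if in_baseline.sum() < 3:
        raise ValueError("baseline must span at least 3 bins")
    fit = stats.linregress(centers[in_baseline], binned[in_baseline])
    detrended = binned - (fit.intercept + fit.slope * centers)
    cvm = np.cumsum(detrended)

    def value_at(t: float) -> float | None:
        if t is None or t > right[-1] + bin_s / 2 + 1e-9:
            return None
        i = int(np.clip(round(t / bin_s) - 1, 0, n_bins - 1))
        return float(cvm[i])

    t1 = trace.stim_offset
    t2 = t1 + T2_DELAY_S
    v2 = value_at(t2)
    return CvmCurve(
        time=right,
        cvm=cvm,
        bin_s=bin_s,
        baseline_window=(b0, b1),
        t1=t1,
        t2=t2 if v2 is not None else None,
        value_t1=value_at(t1),
        value_t2=v2,
        condition=trace.condition,
    )


def _check_matched(a: CvmCurve, b: CvmCurve) -> None:
    if abs(a.t1 - b.t1) > 1e-6 or abs(a.bin_s - b.bin_s) > 1e-9:
        raise ValueError("cVm curves have mismatched stimulation windows")


def nmdar_component(control: CvmCurve, blocked: CvmCurve) -> float:
    """NMDAR-mediated share of the evoked cVm change at t1 (mV).

    Difference between the control response and the response with NMDARs
    blocked pharmacologically (e.g. dAP5 or intracellular MK-801).
    """
    _check_matched(control, blocked)
    return control.value_t1 - blocked.value_t1


def supralinearity(
    observed: CvmCurve, part_a: CvmCurve, part_b: CvmCurve
) -> tuple[float, float, float]:
    """Observed vs expected cVm at t1 for a paired stimulation.

    ``expected`` is the arithmetic sum of the two component responses
    measured alone; a positive ``delta = observed - expected`` flags
    supralinear integration.
    """
    _check_matched(observed, part_a)
    _check_matched(observed, part_b)
    expected = part_a.value_t1 + part_b.value_t1
    obs = observed.value_t1
    return obs, expected, obs - expected
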