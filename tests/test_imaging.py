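"""Imaging pipeline: QC, F0/ΔF/F, transient detection, spatial FWHM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearcalc import imaging
from fearcalc.imaging import (
    CalciumEvent,
    DffTrace,
    RoiTraceSet,
    classify_event,
    compute_dff,
    detect_transients,
    double_exp_kernel,
    event_frequency,
    qc_frames,
    rolling_f0,
    spatial_fwhm,
)

FP = 0.256  # axonal frame period, s


def make_dff(x, frame_period=FP):
    x = np.asarray(x, float)
    return DffTrace(x, np.ones_like(x), frame_period, np.zeros(len(x), bool))


# ---------------------------------------------------------------------------
# frame QC
# ---------------------------------------------------------------------------

def test_identical_frames_all_retained():
    rng = np.random.default_rng(0)
    frame = rng.random((16, 16))
    movie = np.repeat(frame[None], 10, axis=0)
    assert qc_frames(movie).all()


def test_independent_noise_frame_masked():
    rng = np.random.default_rng(1)
    frame = rng.random((16, 16))
    movie = np.repeat(frame[None], 10, axis=0) + rng.normal(0, 0.01, (10, 16, 16))
    movie[4] = rng.random((16, 16))  # unrelated content
    mask = qc_frames(movie)
    assert not mask[4]
    assert mask.sum() == 9


def test_shot_noise_alone_retains_all_frames():
    rng = np.random.default_rng(2)
    frame = 100.0 + 50.0 * rng.random((16, 16))
    for seed in range(20):
        r = np.random.default_rng(seed)
        movie = frame[None] + r.normal(0, 10.0, (12, 16, 16))
        assert qc_frames(movie).all()


def test_constant_movie_keeps_all_frames_with_warning():
    with pytest.warns(UserWarning):
        mask = qc_frames(np.ones((5, 8, 8)))
    assert mask.all()


# ---------------------------------------------------------------------------
# rolling F0 / dff
# ---------------------------------------------------------------------------

def test_f0_of_constant_trace_is_the_constant():
    f0, warm = rolling_f0(np.full(40, 7.5), FP)
    assert np.allclose(f0, 7.5)
    assert warm[:10].all() and not warm[12:].any()


def test_f0_of_alternating_trace_is_lower_value():
    # full 12-frame window holds six of each: lower half = all a
    f0, warm = rolling_f0(np.tile([2.0, 4.0], 30), FP)
    assert np.allclose(f0[~warm], 2.0)


def test_f0_lags_step_by_at_most_one_window():
    x = np.concatenate([np.full(30, 10.0), np.full(30, 20.0)])
    f0, _ = rolling_f0(x, FP, window_s=3.0)
    w = int(round(3.0 / FP))
    assert np.allclose(f0[30 + w :], 20.0)  # converged after one window
    dff = (x - f0) / f0
    assert dff[30] > 0  # transiently positive right after the step
    assert np.allclose(dff[30 + w :], 0.0)


def test_f0_window_must_span_four_frames():
    with pytest.raises(ValueError):
        rolling_f0(np.ones(50), frame_period=1.0, window_s=3.0)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(1.0, 100.0), min_size=15, max_size=40),
    st.integers(0, 14),
    st.floats(0.5, 50.0),
)
def test_f0_monotone_in_past_values(values, idx, bump):
    """Raising any past fluorescence value never lowers F0."""
    x = np.asarray(values)
    f0a, _ = rolling_f0(x, FP)
    y = x.copy()
    y[idx] += bump
    f0b, _ = rolling_f0(y, FP)
    assert (f0b >= f0a - 1e-9).all()


def test_dff_identities_and_error():
    x = np.full(20, 3.0)
    d = compute_dff(x, np.full(20, 3.0), FP)
    assert np.allclose(d.dff, 0.0)
    d = compute_dff(2 * x, x, FP)
    assert np.allclose(d.dff, 1.0)
    with pytest.raises(ValueError, match="roi007"):
        compute_dff(x, np.zeros(20), FP, roi_id="roi007")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_threshold_boundary_on_noiseless_template():
    k = double_exp_kernel(0.1, 0.8, FP)
    n = 200
    sd = 0.1
    for mult, expected in [(2.9, 0), (3.1, 1)]:
        x = np.zeros(n)
        x[100 : 100 + len(k)] = mult * sd * k
        events = detect_transients(make_dff(x), background_sd=sd)
        assert len(events) == expected, mult
    if expected:
        assert events[0].amplitude_dff == pytest.approx(3.1 * sd, rel=0.05)


def test_detection_invariant_to_raw_trace_scaling():
    rng = np.random.default_rng(3)
    k = double_exp_kernel(0.05, 0.4, FP)
    f = 100.0 * (1.0 + rng.normal(0, 0.05, 300))
    for t in (20, 45):
        f[t : t + len(k)] += 100.0 * 0.5 * k[: 300 - t]
    events_by_scale = []
    for scale in (1.0, 3.7):
        x = scale * f
        f0, warm = rolling_f0(x, FP)
        d = compute_dff(x, f0, FP, warm)
        events_by_scale.append(detect_transients(d))
    a, b = events_by_scale
    assert [e.peak_s for e in a] == [e.peak_s for e in b]
    assert np.allclose(
        [e.amplitude_dff for e in a], [e.amplitude_dff for e in b]
    )


def test_trace_shorter_than_template_rejected():
    with pytest.raises(ValueError):
        detect_transients(make_dff(np.zeros(5)))


def test_warmup_frames_never_host_events():
    k = double_exp_kernel(0.05, 0.4, FP)
    x = np.zeros(120)
    x[2 : 2 + len(k)] = 1.0 * k  # huge event inside the warm-up window
    warm = np.zeros(120, bool)
    warm[:12] = True
    d = DffTrace(x, np.ones(120), FP, warm)
    events = detect_transients(d, background_sd=0.05)
    assert all(e.peak_s >= 12 * FP for e in events)


# ---------------------------------------------------------------------------
# spatial FWHM and classification
# ---------------------------------------------------------------------------

def gaussian_profile_traces(sigma_um, length_um=120.0, n_rois=60, amp=1.0):
    pos = np.linspace(1.0, length_um - 1.0, n_rois)
    profile = amp * np.exp(-((pos - length_um / 2) ** 2) / (2 * sigma_um**2))
    dff = np.zeros((n_rois, 40))
    dff[:, 20] = profile
    traces = RoiTraceSet(
        fluorescence=100.0 * (1 + dff),
        frame_period=0.032,
        positions_um=pos,
        pixel_size_um=1.0,
    )
    return traces, dff


def test_noiseless_gaussian_profile_recovers_closed_form_fwhm():
    for sigma in (5.0, 10.0, 20.0):
        traces, dff = gaussian_profile_traces(sigma)
        ev = CalciumEvent("d", 0.6, 20 * 0.032, 1.0, 1.0)
        ev = spatial_fwhm(traces, dff, ev)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert ev.fwhm_um == pytest.approx(expected, rel=0.02)
        assert ev.fwhm_pct_length == pytest.approx(100 * ev.fwhm_um / traces.dendrite_length_um)


def test_flat_profile_forces_global_label():
    traces, dff = gaussian_profile_traces(sigma_um=1e4)  # effectively flat
    ev = CalciumEvent("d", 0.6, 20 * 0.032, 1.0, 1.0)
    ev = spatial_fwhm(traces, dff, ev)
    assert ev.fwhm_um >= traces.dendrite_length_um
    assert ev.label == "global"


def test_too_few_rois_rejected():
    traces, dff = gaussian_profile_traces(10.0, n_rois=4)
    with pytest.raises(ValueError):
        spatial_fwhm(traces, dff, CalciumEvent("d", 0.6, 0.64, 1.0, 1.0))


@pytest.mark.parametrize(
    "fwhm,expected", [(13.5, "local"), (49.99, "local"), (50.0, "global"), (81.0, "global")]
)
def test_local_global_boundary_at_50_um(fwhm, expected):
    ev = CalciumEvent("d", 0.0, 0.0, 1.0, 1.0, fwhm_um=fwhm)
    assert classify_event(ev) == expected


def test_event_frequency_arithmetic():
    events = [CalciumEvent("r", 0, t, 0.5, 1.0) for t in (5.0, 12.0, 29.0)]
    assert event_frequency(events, (0.0, 30.0)) == pytest.approx(0.1)
    assert event_frequency([], (0.0, 30.0)) == 0.0
    assert event_frequency(events, (100.0, 130.0)) == 0.0
    with pytest.raises(ValueError):
        event_frequency(events, (10.0, 10.0))
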