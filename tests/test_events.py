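import numpy as np
import pytest
from scipy import signal

import coactivity as ca
from coactivity.events import (
    DetectionParams,
    TraceSet,
    detect_events,
    estimate_sigma,
    lowpass_fir,
    preprocess_trace,
)


def test_preprocess_cancels_surround_and_offsets():
    rng = np.random.default_rng(0)
    surround = 1.0 + rng.normal(0, 0.01, (3, 400))
    # roi == surround -> corrected signal identically 0
    dff = preprocess_trace(TraceSet(surround.copy(), surround.copy()))
    assert np.allclose(dff, 0.0, atol=1e-12)
    # a shared constant offset cancels in the subtraction
    dff2 = preprocess_trace(TraceSet(surround + 5.0, surround + 5.0))
    assert np.allclose(dff2, 0.0, atol=1e-12)


def test_preprocess_rejects_nonfinite():
    roi = np.ones((1, 300))
    roi[0, 5] = np.nan
    with pytest.raises(ValueError):
        preprocess_trace(TraceSet(roi, np.ones((1, 300))))


def test_lowpass_attenuates_stopband():
    """White noise filtered zero-phase loses >= 25 dB above the stopband edge."""
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1.0, (1, 8192))
    taps = lowpass_fir()
    y = signal.filtfilt(taps, [1.0], x, axis=1)
    f, pxx_in = signal.periodogram(x[0])
    _, pxx_out = signal.periodogram(y[0])
    stop = f > 0.65 / 2  # periodogram frequencies are cycles/sample; Nyquist=0.5
    atten_db = 10 * np.log10(pxx_in[stop].mean() / pxx_out[stop].mean())
    assert atten_db >= 25.0
    passband = (f > 0.01) & (f < 0.5 / 2 * 0.8)
    ripple_db = abs(10 * np.log10(pxx_out[passband].mean() / pxx_in[passband].mean()))
    assert ripple_db < 3.0


def test_estimate_sigma_matches_brute_force_definition():
    """Gaussian noise: sigma equals the sd over the least-active half, computed
    independently, and sits within 15% of that selection's sd."""
    rng = np.random.default_rng(2)
    x = rng.normal(0, 0.02, 4000)
    params = DetectionParams()
    got = estimate_sigma(x, params)
    # brute-force oracle: same definition, written out directly
    w = 20
    sm = np.convolve(np.abs(x), np.ones(w) / w, mode="same")
    # uniform_filter1d(mode="nearest") differs at the edges; ignore them
    quiet = np.argsort(sm[w:-w], kind="stable")[: 4000 // 2] + w
    oracle = np.std(x[quiet])
    assert got == pytest.approx(oracle, rel=0.15)


def test_estimate_sigma_ignores_transients_and_flags_constant():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.01, 4000)
    x[500:900] += 0.5  # large transients in 10% of frames
    sig = estimate_sigma(x)
    assert sig == pytest.approx(0.01, rel=0.2)
    assert estimate_sigma(np.full(500, 1.23)) == 0.0
    row, events = detect_events(np.full(500, 1.23), 0.0)
    assert row.sum() == 0 and events == []


def test_detect_single_noiseless_transient_active_window():
    """One large transient with AUC above 250 sigma-frames: exactly one
    event, active until the signal falls to 70% of the peak (hand-computed
    crossing) or 40 frames."""
    sigma = 0.01
    tau = 10.0  # 0.5 s at 20 Hz; amplitude 30 sigma puts the AUC over 250
    x = np.zeros(400)
    onset, rise = 100, 2
    x[onset + 1 : onset + rise + 1] = [0.15, 0.3]
    t = np.arange(400 - (onset + rise + 1))
    x[onset + rise + 1 :] = 0.3 * np.exp(-(t + 1) / tau)
    row, events = detect_events(x, sigma)
    assert len(events) == 1
    ev_onset, ev_end, peak = events[0]
    assert peak == pytest.approx(0.3)
    # signal <= 0.7*peak first at ceil(tau*ln(1/0.7)) frames after the peak
    peak_frame = onset + rise
    expect_end = peak_frame + 1 + int(np.ceil(tau * np.log(1 / 0.7))) - 1
    assert abs(ev_end - min(expect_end, ev_onset + 40)) <= 1
    assert row[ev_onset:ev_end].all() and row.sum() == ev_end - ev_onset


def test_detection_thresholds_are_monotone():
    """Raising any threshold never increases the number of detected events."""
    rng = np.random.default_rng(4)
    tmpl = ca.TransientTemplate(amplitude=22.0, rise_frames=2, decay_tau=15.0,
                                noise_sd=0.005)
    blocks = [(0, s, 20) for s in range(100, 3800, 250)]
    traces, _ = ca.gen_traces(blocks, tmpl, 4000, 1, seed=5)
    x = traces[0] + rng.normal(0, 0.005, 4000)
    sigma = estimate_sigma(x)
    base = len(detect_events(x, sigma)[1])
    assert base > 0
    for field, factor in [("rise_threshold", 2), ("confirm_threshold", 1.5),
                          ("auc_threshold", 2), ("abs_peak_min", 10)]:
        params = DetectionParams(**{field: getattr(DetectionParams(), field) * factor})
        assert len(detect_events(x, sigma, params)[1]) <= base


def test_detection_scale_invariance():
    """Multiplying trace and sigma jointly leaves detections unchanged
    (above the absolute dF/F0 floor)."""
    tmpl = ca.TransientTemplate(amplitude=25.0, rise_frames=2, decay_tau=15.0,
                                noise_sd=0.005)
    traces, _ = ca.gen_traces([(0, 100, 20), (0, 500, 20)], tmpl, 900, 1, seed=6)
    x = traces[0]
    sigma = estimate_sigma(x)
    row1, ev1 = detect_events(x, sigma)
    row2, ev2 = detect_events(4.0 * x, 4.0 * sigma)
    assert np.array_equal(row1, row2)
    assert [(a, b) for a, b, _ in ev1] == [(a, b) for a, b, _ in ev2]


def test_detect_events_raster_end_to_end():
    tmpl = ca.TransientTemplate(amplitude=25.0, rise_frames=2, decay_tau=15.0,
                                noise_sd=0.005)
    rng = np.random.default_rng(7)
    blocks = [(0, 200, 20), (1, 600, 20)]
    sig, truth = ca.gen_traces(blocks, tmpl, 1000, 2, seed=8)
    surround = 1.0 + rng.normal(0, 0.002, (2, 1000))
    raster, sigmas = ca.detect_events_raster(TraceSet(surround + sig, surround))
    assert raster.shape == (2, 1000)
    assert (sigmas > 0).all()
    assert raster[0, 200:210].any() and raster[1, 600:610].any()
    assert not raster[0, 600:650].any() and not raster[1, 200:250].any()
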