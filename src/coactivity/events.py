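"""Threshold-cascade calcium event detection on surround-corrected traces.

The cascade converts a dF/F0 trace into a binary raster row:

1. candidate onsets where the signal rises >= 3 sigma within 1 s;
2. candidates kept only if the rise reaches >= 15 sigma within 2 s of onset,
   the event's area under the curve is >= 250 sigma-frames, and the peak
   exceeds an absolute dF/F0 floor of 0.0125;
3. the neuron is marked active from onset until the signal drops 30% from the
   event peak, capped at 2 s.

sigma is the dF/F0 standard deviation over the least active 50% of the movie,
so it tracks baseline noise rather than transient amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .raster import FRAME_RATE_HZ


@dataclass
class TraceSet:
    """Per-neuron ROI-mean and surround-mean fluorescence time series."""

    roi: np.ndarray       # (n_neurons, n_frames)
    surround: np.ndarray  # (n_neurons, n_frames)
    frame_rate: float = FRAME_RATE_HZ

    def __post_init__(self) -> None:
        self.roi = np.atleast_2d(np.asarray(self.roi, dtype=np.float64))
        self.surround = np.atleast_2d(np.asarray(self.surround, dtype=np.float64))
        if self.roi.shape != self.surround.shape:
            raise ValueError("roi and surround traces must have equal shapes")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class DetectionParams:
    """Thresholds of the detection cascade (sigma units unless noted)."""

    rise_threshold: float = 3.0       # sigma, within rise_window_s
    rise_window_s: float = 1.0
    confirm_threshold: float = 15.0   # sigma, within confirm_window_s of onset
    confirm_window_s: float = 2.0
    auc_threshold: float = 250.0      # sigma * frames (at 20 Hz)
    abs_peak_min: float = 0.0125      # absolute dF/F0 floor
    decay_fraction: float = 0.30      # active until signal drops this far from peak
    max_active_s: float = 2.0
    sigma_quantile: float = 0.5       # least-active fraction of the movie
    smooth_window_s: float = 1.0      # |dF/F0| smoothing used to rank frames

    def __post_init__(self) -> None:
        for name in ("rise_threshold", "confirm_threshold", "auc_threshold", "abs_peak_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.decay_fraction < 1.0:
            raise ValueError("decay_fraction must lie in (0, 1)")


def lowpass_fir(
    passband: float = 0.5,
    stopband: float = 0.65,
    attenuation_db: float = 25.0,
) -> np.ndarray:
    """Linear-phase FIR low-pass filter taps (frequencies normalized to Nyquist)."""
    numtaps, beta = signal.kaiserord(attenuation_db, stopband - passband)
    numtaps |= 1  # odd length keeps the group delay an integer number of frames
    return signal.firwin(numtaps, (passband + stopband) / 2.0, window=("kaiser", beta))


def preprocess_trace(traces: TraceSet) -> np.ndarray:
    """Surround-subtract, normalize to dF/F0, and low-pass filter.

    The corrected signal is ``roi - surround``; F0 is the median of the
    surround signal per neuron.  The filter is applied zero-phase.
    """
    if not (np.isfinite(traces.roi).all() and np.isfinite(traces.surround).all()):
        raise ValueError("traces contain non-finite samples")
    corrected = traces.roi - traces.surround
    f0 = np.median(traces.surround, axis=1, keepdims=True)
    if (f0 <= 0).any():
        raise ValueError("surround median (F0) must be positive for dF/F0 normalization")
    dff = corrected / f0
    taps = lowpass_fir()
    if dff.shape[1] <= 3 * len(taps):
        # short traces: shrink the filter rather than refuse to run
        taps = lowpass_fir(attenuation_db=25.0)[: max(dff.shape[1] // 3, 3)]
        taps = taps / taps.sum()
    return signal.filtfilt(taps, [1.0], dff, axis=1)


def estimate_sigma(dff: np.ndarray, params: DetectionParams | None = None,
                   frame_rate: float = FRAME_RATE_HZ) -> float:
    """Noise sd over the least-active half of the movie.

    Frames are ranked by their 1 s moving average of |dF/F0|; sigma is the
    standard deviation of the raw signal over the lowest ``sigma_quantile``
    fraction.  A constant trace yields sigma = 0, which disables detection.
    """
    params = params or DetectionParams()
    dff = np.asarray(dff, dtype=np.float64)
    if dff.ndim != 1:
        raise ValueError("estimate_sigma expects a single trace")
    if dff.size < 100:
        raise ValueError("trace too short to estimate sigma (need >= 100 frames)")
    w = max(int(round(params.smooth_window_s * frame_rate)), 1)
    smoothed = uniform_filter1d(np.abs(dff), size=w, mode="nearest")
    n_keep = max(int(round(params.sigma_quantile * dff.size)), 2)
    quiet = np.argsort(smoothed, kind="stable")[:n_keep]
    sd = float(np.std(dff[quiet]))
    if sd < 1e-10 * max(1.0, float(np.abs(dff).max())):
        return 0.0  # degenerate (constant) trace: detection disabled
    return sd


def detect_events(
    dff: np.ndarray,
    sigma: float,
    params: DetectionParams | None = None,
    frame_rate: float = FRAME_RATE_HZ,
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Run the threshold cascade on one trace.

    Returns ``(active_row, events)`` where ``events`` is a list of
    ``(onset_frame, active_end_frame, peak_value)``.  With sigma <= 0 the
    trace is treated as undetectable and an empty row is returned.
    """
    params = params or DetectionParams()
    x = np.asarray(dff, dtype=np.float64)
    n = x.size
    active = np.zeros(n, dtype=np.uint8)
    events: list[tuple[int, int, float]] = []
    if sigma <= 0 or n == 0:
        return active, events

    w1 = max(int(round(params.rise_window_s * frame_rate)), 1)
    w2 = max(int(round(params.confirm_window_s * frame_rate)), 1)
    w_active = max(int(round(params.max_active_s * frame_rate)), 1)

    # rise within the trailing 1 s window ending at each frame
    rolled_min = np.empty(n)
    for t in range(n):
        rolled_min[t] = x[max(0, t - w1 + 1) : t + 1].min()
    rise = x - rolled_min
    candidates = np.flatnonzero(rise >= params.rise_threshold * sigma)

    blocked_until = -1  # frames up to here belong to an already-processed event
    for t in candidates:
        if t <= blocked_until:
            continue
        window = x[max(0, t - w1 + 1) : t + 1]
        onset = int(max(0, t - w1 + 1) + np.argmin(window))
        # pre-event baseline: median of the samples just before the onset
        # (robust to the onset frame itself being a low noise excursion)
        baseline = float(np.median(x[max(0, onset - w1 // 2) : onset + 1]))
        # event extent: until the signal returns to the pre-event baseline
        below = np.flatnonzero(x[onset + 1 :] <= baseline)
        extent_end = int(onset + 1 + below[0]) if below.size else n
        peak_rel = int(np.argmax(x[onset:extent_end]))
        peak_frame = onset + peak_rel
        peak = float(x[peak_frame])
        blocked_until = extent_end - 1

        confirm = x[onset : min(onset + w2 + 1, n)].max() - baseline
        if confirm < params.confirm_threshold * sigma:
            continue
        auc = float(np.sum(x[onset:extent_end] - baseline))
        if auc < params.auc_threshold * sigma:
            continue
        if peak < params.abs_peak_min:
            continue

        # active until the signal has dropped decay_fraction from the peak,
        # capped at max_active_s after onset
        drop_level = peak - params.decay_fraction * peak
        dropped = np.flatnonzero(x[peak_frame:extent_end] <= drop_level)
        if dropped.size:
            active_end = peak_frame + int(dropped[0])
        else:
            active_end = extent_end
        active_end = min(active_end, onset + w_active, n)
        active_end = max(active_end, onset + 1)
        active[onset:active_end] = 1
        events.append((onset, active_end, peak))
    return active, events


def detect_events_raster(
    traces: TraceSet, params: DetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full cascade over a trace set: preprocess, estimate sigma, detect.

    Returns ``(raster, sigmas)``; neurons with degenerate (sigma = 0) traces
    produce empty rows.
    """
    params = params or DetectionParams()
    dff = preprocess_trace(traces)
    n_neurons = dff.shape[0]
    raster = np.zeros(dff.shape, dtype=np.uint8)
    sigmas = np.zeros(n_neurons)
    for i in range(n_neurons):
        sigmas[i] = estimate_sigma(dff[i], params, traces.frame_rate)
        raster[i], _ = detect_events(dff[i], sigmas[i], params, traces.frame_rate)
    return raster, sigmas
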