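"""Offline ECG analysis.

Band-pass filtering (1-40 Hz zero-phase FIR, Hamming window), adaptive
R-peak detection, heart rate and RMSSD, per-beat R amplitude and T-wave
area, and post-hoc cardiac-phase coding of arbitrary event times against
the beat-wise end-of-T boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import CardiacTimeline, t_end_from_rr

__all__ = [
    "bandpass_ecg",
    "ecg_bandpass_taps",
    "detect_r_peaks",
    "compute_hr_hrv",
    "code_cardiac_phase",
    "cardiac_features",
    "timeline_from_r_times",
]


def ecg_bandpass_taps(fs: float, low: float = 1.0, high: float = 40.0) -> np.ndarray:
    """Linear-phase Hamming-window FIR band-pass design for ECG."""
    if fs <= 80:
        raise ValueError("fs must exceed 80 Hz for a 1-40 Hz band-pass")
    numtaps = int(3.3 * fs) | 1  # ~1 Hz transition width at the low edge
    return sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass_ecg(x: np.ndarray, fs: float, low: float = 1.0, high: float = 40.0) -> np.ndarray:
    """Zero-phase 1-40 Hz band-pass.

    The FIR is symmetric (linear phase), so a single overlap-add
    convolution with centered alignment is exactly zero-phase.
    """
    taps = ecg_bandpass_taps(fs, low, high)
    return sps.oaconvolve(np.asarray(x, dtype=float), taps, mode="same")


def detect_r_peaks(x: np.ndarray, fs: float, refractory_s: float = 0.25) -> np.ndarray:
    """Adaptive-threshold R-peak detection.

    Local maxima above half the 99.9th amplitude percentile, separated by a
    refractory period. The threshold scales with the signal, so detection
    times are invariant to amplitude scaling. Returns peak times in
    seconds; a flat or non-positive signal yields no detections.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0 or np.ptp(x) == 0:
        return np.empty(0)
    thr = 0.5 * np.percentile(x, 99.9)
    if thr <= 0:
        return np.empty(0)
    peaks, _ = sps.find_peaks(x, height=thr, distance=max(int(refractory_s * fs), 1))
    return peaks / fs


def compute_hr_hrv(rr_intervals_ms: np.ndarray) -> tuple[float, float]:
    """Mean heart rate (bpm) and RMSSD (ms) from RR intervals.

    hr = 60000 / mean(RR); rmssd = sqrt(mean(successive-difference^2)).
    RMSSD is NaN (flagged missing) with fewer than two intervals.
    """
    rr = np.asarray(rr_intervals_ms, dtype=float)
    rr = rr[np.isfinite(rr)]
    if len(rr) == 0:
        return float("nan"), float("nan")
    hr = 60000.0 / rr.mean()
    if len(rr) < 2:
        return float(hr), float("nan")
    d = np.diff(rr)
    return float(hr), float(np.sqrt(np.mean(d**2)))


def timeline_from_r_times(r_times_s: np.ndarray) -> CardiacTimeline:
    """Build a cardiac timeline (with HR-adaptive T-end estimates) from
    detected R-peak times."""
    r = np.asarray(r_times_s, dtype=float)
    rr = np.diff(r) * 1000.0
    if len(rr):
        rr_for_beat = np.concatenate([rr, rr[-1:]])
    else:
        rr_for_beat = np.array([1000.0])
    return CardiacTimeline(r, rr, t_end_from_rr(rr_for_beat))


def code_cardiac_phase(
    event_times_s: np.ndarray | float, timeline: CardiacTimeline
) -> np.ndarray:
    """Classify events as systole (R-peak to end of T wave, inclusive of
    both bounds at R and T-end) or diastole (after T-end, before the next
    R). Events before the first R-peak are coded 'unknown'."""
    t = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    idx = timeline.preceding_beat(t)
    out = np.full(len(t), "unknown", dtype=object)
    ok = idx >= 0
    offs = (t[ok] - timeline.r_peak_times[idx[ok]]) * 1000.0
    t_end = timeline.t_end_offsets[idx[ok]]
    out[ok] = np.where(offs <= t_end + 1e-6, "systole", "diastole")
    return out


def cardiac_features(
    ecg: np.ndarray,
    fs: float,
    r_times_s: np.ndarray,
    t_window_ms: tuple[float, float] = (240.0, 340.0),
) -> pd.DataFrame:
    """Per-beat R-peak amplitude and T-wave area.

    R amplitude is the maximum within a +/-1 sample window around the
    detected peak. T-wave area is the trapezoidal area under the curve in
    ``t_window_ms`` after the R-peak (uV*ms).
    """
    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    rows = []
    for t in np.atleast_1d(r_times_s):
        i = int(round(t * fs))
        if i < 1 or i + 2 > n:
            continue
        r_amp = float(ecg[i - 1 : i + 2].max())
        j0 = i + int(round(t_window_ms[0] * fs / 1000.0))
        j1 = i + int(round(t_window_ms[1] * fs / 1000.0))
        if j1 >= n:
            t_area = float("nan")
        else:
            t_area = float(np.trapezoid(ecg[j0 : j1 + 1], dx=1000.0 / fs))
        rows.append((t, r_amp, t_area))
    return pd.DataFrame(rows, columns=["r_time_s", "r_amplitude_uv", "t_area_uv_ms"])
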