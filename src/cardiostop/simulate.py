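"""Fully synthetic sessions with known ground truth.

This module generates everything downstream stages consume: an RR-interval
series with controlled mean heart rate and RMSSD, an ECG trace rendered from
a parametric beat template, a race-model agent behaving in the stop-signal
task, and multichannel EEG built as a linear superposition of event-locked
ERP templates, an R-locked cardiac field artifact, and white noise.

Because every injected component is known, each analysis stage can be
validated by recovery: R-peak detection against true beat times, SSRT
estimation against the agent's true stopping latency, ROI amplitudes and
cluster tests against the injected template gains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import CONDITIONS, RaceModelParams, SessionConfig
from .montage import gaussian_scalp_pattern, load_montage, subset_montage

__all__ = [
    "CardiacTimeline",
    "EcgSignal",
    "ErpTemplate",
    "SimulatedSession",
    "simulate_rr_series",
    "synthesize_ecg",
    "sample_race_outcome",
    "simulate_race_trials",
    "render_eeg",
    "simulate_session",
    "default_templates",
    "default_cfa_waveform",
    "cfa_pattern",
    "ECG_BUMPS",
    "T_END_BASE_MS",
]

# End of the T wave, ms after the R-peak, for a 1000 ms RR interval.
# Defined as T-center + 2 * T-width of the beat template below; scaled per
# beat by sqrt(RR/1000) to mimic rate-dependent repolarization timing.
T_END_BASE_MS = 350.0

# ECG beat template: Gaussian bumps (amplitude uV, center ms relative to R,
# width ms, whether the timing scales with sqrt(RR/1000)).
ECG_BUMPS = (
    ("P", 90.0, -180.0, 25.0, True),
    ("Q", -120.0, -30.0, 9.0, False),
    ("R", 1100.0, 0.0, 11.0, False),
    ("S", -250.0, 35.0, 10.0, False),
    ("T", 220.0, 290.0, 30.0, True),
)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class CardiacTimeline:
    """R-peak times and RR intervals; the clock for cardiac-coupled events.

    ``t_end_offsets`` gives the per-beat end-of-T estimate in ms after the
    R-peak: the boundary between the beat's systolic (R to T-end) and
    diastolic (T-end to next R) windows.
    """

    r_peak_times: np.ndarray  # seconds, strictly increasing
    rr_intervals: np.ndarray  # ms, len == n_beats - 1
    t_end_offsets: np.ndarray  # ms, len == n_beats

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        self.t_end_offsets = np.asarray(self.t_end_offsets, dtype=float)
        n = len(self.r_peak_times)
        if n >= 2:
            if np.any(np.diff(self.r_peak_times) <= 0):
                raise ValueError("r_peak_times must be strictly increasing")
            implied = np.diff(self.r_peak_times) * 1000.0
            if np.max(np.abs(implied - self.rr_intervals)) > 1e-6:
                raise ValueError("rr_intervals inconsistent with r_peak_times")
            if np.any(self.t_end_offsets[:-1] >= self.rr_intervals):
                raise ValueError("t_end_offset must be shorter than its RR interval")
        if len(self.t_end_offsets) != n:
            raise ValueError("t_end_offsets must have one entry per beat")

    @property
    def n_beats(self) -> int:
        return len(self.r_peak_times)

    def truncate(self, t_max: float) -> "CardiacTimeline":
        """Timeline restricted to beats at or before ``t_max`` seconds."""
        keep = self.r_peak_times <= t_max
        n = int(keep.sum())
        return CardiacTimeline(
            self.r_peak_times[:n],
            self.rr_intervals[: max(n - 1, 0)],
            self.t_end_offsets[:n],
        )

    def preceding_beat(self, t: float | np.ndarray) -> np.ndarray:
        """Index of the R-peak at or before each time (-1 if none)."""
        return np.searchsorted(self.r_peak_times, np.atleast_1d(t), side="right") - 1


def t_end_from_rr(rr_ms: np.ndarray) -> np.ndarray:
    """HR-adaptive end-of-T estimate: T_END_BASE_MS * sqrt(RR/1000), capped
    below the RR interval itself."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    return np.minimum(T_END_BASE_MS * np.sqrt(rr_ms / 1000.0), 0.95 * rr_ms)


def simulate_rr_series(
    mean_hr_bpm: float,
    rmssd_ms: float,
    n_beats: int,
    rng: np.random.Generator | int | None = None,
    phi: float = 0.5,
    start_time: float = 1.0,
) -> CardiacTimeline:
    """Draw an RR series as a lag-1 autocorrelated Gaussian process.

    The process variance is calibrated so the expected RMSSD equals
    ``rmssd_ms``: for a stationary AR(1) with autocorrelation ``phi``,
    E[(RR_{i+1} - RR_i)^2] = 2 * var * (1 - phi), hence
    var = rmssd^2 / (2 * (1 - phi)). Non-positive RR draws are resampled
    (vanishingly rare at physiological settings).
    """
    if not 30.0 < mean_hr_bpm < 180.0:
        raise ValueError("mean_hr_bpm must lie in (30, 180)")
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    if rmssd_ms < 0:
        raise ValueError("rmssd_ms must be non-negative")
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1)")
    rng = _as_rng(rng)
    mu = 60000.0 / mean_hr_bpm
    sigma_x = rmssd_ms / math.sqrt(2.0 * (1.0 - phi))
    if sigma_x > mu / 3.0:
        raise ValueError(
            f"rmssd_ms={rmssd_ms} is too large for mean RR {mu:.0f} ms "
            "(would imply frequent non-physiological intervals)"
        )
    sigma_e = sigma_x * math.sqrt(1.0 - phi**2)
    x = np.empty(n_beats)
    x[0] = rng.normal(0.0, sigma_x) if sigma_x > 0 else 0.0
    for i in range(1, n_beats):
        x[i] = phi * x[i - 1] + (rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0)
    rr = mu + x
    bad = np.flatnonzero(rr <= 0)
    for i in bad:  # resample offending innovations until positive
        while rr[i] <= 0:
            rr[i] = mu + phi * (rr[i - 1] - mu if i > 0 else 0.0) + rng.normal(0.0, sigma_e)
    # rr[i] is the interval *between* beat i and beat i+1; the last value is
    # kept only to derive the final beat's T-end estimate.
    intervals = rr[:-1]
    times = start_time + np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    t_end = t_end_from_rr(rr)
    return CardiacTimeline(times, intervals, t_end)


@dataclass
class EcgSignal:
    samples: np.ndarray  # uV
    fs: float
    true_r_indices: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.true_r_indices = np.asarray(self.true_r_indices, dtype=int)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.true_r_indices) and (
            self.true_r_indices.min() < 0 or self.true_r_indices.max() >= len(self.samples)
        ):
            raise ValueError("true_r_indices out of bounds")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def synthesize_ecg(
    timeline: CardiacTimeline,
    fs: float = 500.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    duration: float | None = None,
) -> EcgSignal:
    """Render an ECG trace from the beat template at each R-peak.

    Each beat contributes Gaussian P/Q/R/S/T deflections; P and T timings
    scale with sqrt(RR/1000). Beats whose template support would overlap a
    neighbouring beat are truncated at a fraction of the local RR interval
    (with a warning), so very short intervals stay renderable.
    """
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz for QRS rendering")
    rng = _as_rng(rng)
    r = timeline.r_peak_times
    if duration is None:
        duration = float(r[-1]) + 0.8
    n = int(math.ceil(duration * fs))
    x = np.zeros(n)
    rr = timeline.rr_intervals
    truncated = False
    for i, t0 in enumerate(r):
        rr_next = rr[i] if i < len(rr) else (rr[-1] if len(rr) else 1000.0)
        rr_prev = rr[i - 1] if i > 0 else rr_next
        scale = math.sqrt(rr_next / 1000.0)
        lo_support = t0 - 0.45 * rr_prev / 1000.0
        hi_support = t0 + 0.95 * rr_next / 1000.0
        for _, amp, center, width, scaled in ECG_BUMPS:
            s = scale if scaled else 1.0
            c = t0 + center * s / 1000.0
            w = width * s / 1000.0
            lo = max(c - 4 * w, lo_support, 0.0)
            hi = min(c + 4 * w, hi_support, duration)
            if lo > c - 2 * w or hi < c + 2 * w:
                truncated = True
            i0, i1 = int(math.ceil(lo * fs)), int(math.floor(hi * fs)) + 1
            if i1 <= i0:
                continue
            tt = np.arange(i0, min(i1, n)) / fs
            x[i0 : i0 + len(tt)] += amp * np.exp(-0.5 * ((tt - c) / w) ** 2)
    if truncated:
        warnings.warn("short RR intervals: some beat deflections were truncated")
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    idx = np.round(r * fs).astype(int)
    idx = idx[idx < n]
    return EcgSignal(x, fs, idx)


# ---------------------------------------------------------------------------
# Race-model agent


def sample_race_outcome(
    params: RaceModelParams,
    ssd_ms: float | None,
    trial_type: str,
    rng: np.random.Generator | int | None = None,
    go_display_ms: float = 1500.0,
) -> tuple[bool, Optional[float]]:
    """One trial of the independent race.

    Go trials: the ex-Gaussian go finishing time is reported unless the go
    process omits or finishes after the response window (both coded as
    omissions). Stop trials: a response occurs iff the go process finishes
    before SSD + SSRT (and did not omit).
    """
    rng = _as_rng(rng)
    out = simulate_race_trials(
        params,
        np.array([np.nan if ssd_ms is None else ssd_ms]),
        np.array([trial_type]),
        rng,
        go_display_ms,
    )
    responded = bool(out["responded"].iloc[0])
    rt = float(out["rt_ms"].iloc[0]) if responded else None
    return responded, rt


def simulate_race_trials(
    params: RaceModelParams,
    ssd_ms: np.ndarray,
    trial_types: np.ndarray,
    rng: np.random.Generator | int | None = None,
    go_display_ms: float = 1500.0,
) -> pd.DataFrame:
    """Vectorized race outcomes for a sequence of trials."""
    rng = _as_rng(rng)
    n = len(trial_types)
    gf = rng.normal(params.go_mu, params.go_sigma, n) + rng.exponential(params.go_tau, n)
    omit = rng.random(n) < params.omission_rate
    ssrt = np.full(n, params.ssrt_true)
    if params.ssrt_sd > 0:
        ssrt += rng.normal(0.0, params.ssrt_sd, n)
    is_stop = np.asarray(trial_types) == "stop"
    ssd = np.asarray(ssd_ms, dtype=float)
    if np.any(is_stop & (np.isnan(ssd) | (ssd < 0))):
        raise ValueError("stop trials require a non-negative ssd_ms")
    responded = ~omit & (gf <= go_display_ms)
    responded[is_stop] &= gf[is_stop] < ssd[is_stop] + ssrt[is_stop]
    rt = np.where(responded, gf, np.nan)
    return pd.DataFrame(
        {
            "trial_type": trial_types,
            "ssd_ms": ssd,
            "responded": responded,
            "rt_ms": rt,
        }
    )


# ---------------------------------------------------------------------------
# EEG forward model


@dataclass
class ErpTemplate:
    """Event-locked scalp component: a Hann-squared bump confined to
    ``window_ms`` after the event, a fixed spatial weight map, and a gain
    per experimental condition."""

    name: str
    event_type: str
    window_ms: tuple[float, float]
    amplitude_uv: float
    channel_weights: np.ndarray
    condition_gains: dict[str, float]
    feedback_kind: Optional[str] = None  # restrict feedback-locked templates

    def __post_init__(self) -> None:
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if not np.all(np.isfinite(self.channel_weights)):
            raise ValueError("channel_weights must be finite")
        t0, t1 = self.window_ms
        if t1 <= t0:
            raise ValueError("window_ms must be increasing")

    def waveform(self, fs: float) -> np.ndarray:
        """Amplitude-scaled waveform sampled at ``fs``; zero at the window
        edges and identically zero outside it."""
        t0, t1 = self.window_ms
        n = int(round((t1 - t0) * fs / 1000.0))
        if n < 2:
            raise ValueError("window too short for sampling rate")
        k = np.arange(n)
        return self.amplitude_uv * np.sin(np.pi * k / (n - 1)) ** 2

    def gain(self, condition: str) -> float:
        return float(self.condition_gains.get(condition, 0.0))


# Stock component geometry: locking event, latency window, peak amplitude,
# scalp-map center labels and angular width, feedback restriction.
TEMPLATE_SPECS: dict[str, dict] = {
    "hep": dict(event_type="r_peak", window_ms=(300.0, 400.0), amplitude_uv=2.0,
                centers=["FCz", "Cz"], sigma_deg=20.0),
    "p2": dict(event_type="distractor_move", window_ms=(200.0, 300.0), amplitude_uv=4.0,
               centers=["FCz"], sigma_deg=30.0),
    "go": dict(event_type="go_cue", window_ms=(200.0, 400.0), amplitude_uv=2.0,
               centers=["Cz"], sigma_deg=25.0),
    "n2": dict(event_type="stop_signal", window_ms=(200.0, 300.0), amplitude_uv=-4.0,
               centers=["Fz", "FCz"], sigma_deg=20.0),
    "p3": dict(event_type="feedback", window_ms=(300.0, 400.0), amplitude_uv=5.0,
               centers=["Cz", "CPz"], sigma_deg=20.0, feedback_kind="commission"),
}


def default_templates(
    montage: pd.DataFrame, gains: dict[str, dict[str, float]]
) -> dict[str, ErpTemplate]:
    """The five stock components injected into simulated sessions.

    HEP: fronto-central, 300-400 ms after each R-peak. P2: fronto-central,
    200-300 ms after each distractor movement onset. Go potential: central,
    equal across conditions. N2: frontal negativity 200-300 ms after the
    stop-signal. P3: centro-parietal, 300-400 ms after commission feedback.
    The montage must contain the scalp-map center electrodes.
    """
    have = set(montage["label"])
    out = {}
    for name, spec in TEMPLATE_SPECS.items():
        missing = [c for c in spec["centers"] if c not in have]
        if missing:
            raise KeyError(
                f"template {name!r} needs center electrode(s) {missing} "
                "not present in the montage subset"
            )
        out[name] = ErpTemplate(
            name,
            spec["event_type"],
            spec["window_ms"],
            spec["amplitude_uv"],
            gaussian_scalp_pattern(montage, spec["centers"], spec["sigma_deg"]),
            gains[name],
            feedback_kind=spec.get("feedback_kind"),
        )
    return out


def template_ground_truth(config: SessionConfig) -> dict:
    """Injected-component metadata (gains, amplitudes, windows) derived
    from the configuration alone."""
    return {
        "template_gains": {k: dict(v) for k, v in config.template_gains.items()},
        "template_amplitudes_uv": {k: s["amplitude_uv"] for k, s in TEMPLATE_SPECS.items()},
        "template_windows_ms": {k: tuple(s["window_ms"]) for k, s in TEMPLATE_SPECS.items()},
        "cfa_gain": config.cfa_gain,
        "noise_sd_uv": config.noise_sd_uv,
    }


def default_cfa_waveform(fs: float) -> tuple[np.ndarray, float]:
    """Cardiac field artifact waveform (uV), R-locked.

    A scaled-down beat shape: sharp QRS deflection plus a broad T-wave bump.
    Returns (waveform, start_ms) where start_ms is the lag of the first
    sample relative to the R-peak.
    """
    start_ms, end_ms = -50.0, 450.0
    t = np.arange(start_ms, end_ms, 1000.0 / fs)
    w = np.zeros_like(t)
    for amp, c, width in ((-1.0, -30.0, 9.0), (6.0, 0.0, 11.0), (-1.5, 35.0, 10.0), (2.0, 290.0, 30.0)):
        w += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return w, start_ms


def cfa_pattern(montage: pd.DataFrame) -> np.ndarray:
    """Spatial map of the cardiac field artifact: a smooth left-right
    gradient with a slight posterior emphasis, as the heart's far field
    projects across the scalp."""
    xyz = montage[["x_cm", "y_cm", "z_cm"]].to_numpy()
    u = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    w = 0.8 * u[:, 0] - 0.4 * u[:, 1] + 0.3
    return w


def render_eeg(
    events: pd.DataFrame,
    templates: dict[str, ErpTemplate] | list[ErpTemplate],
    montage: pd.DataFrame,
    fs: float,
    n_samples: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    cfa_pattern_weights: np.ndarray | None = None,
    cfa_waveform: tuple[np.ndarray, float] | None = None,
    r_peak_times: np.ndarray | None = None,
    cfa_gain: float = 1.0,
    dtype=np.float64,
) -> tuple[np.ndarray, int]:
    """Linear superposition forward model.

    EEG = sum of event-locked templates (scaled by their condition gain)
    + R-locked cardiac field artifact + white Gaussian noise. Events whose
    window falls outside the signal support are skipped and counted.
    Returns (channels x samples array, number of skipped events).
    """
    if isinstance(templates, dict):
        templates = list(templates.values())
    rng = _as_rng(rng)
    n_ch = len(montage)
    eeg = np.zeros((n_ch, n_samples), dtype=dtype)
    skipped = 0
    for tpl in templates:
        if len(tpl.channel_weights) != n_ch:
            raise ValueError(f"template {tpl.name}: channel_weights do not match montage")
        wave = tpl.waveform(fs)
        sel = events[events["event_type"] == tpl.event_type]
        if tpl.feedback_kind is not None and "outcome" in sel.columns:
            sel = sel[sel["outcome"] == tpl.feedback_kind]
        for t, cond in zip(sel["time_s"].to_numpy(), sel["condition"].to_numpy()):
            g = tpl.gain(cond)
            if g == 0.0:
                continue
            s0 = int(round(t * fs)) + int(round(tpl.window_ms[0] * fs / 1000.0))
            if s0 < 0 or s0 + len(wave) > n_samples:
                skipped += 1
                continue
            eeg[:, s0 : s0 + len(wave)] += np.outer(tpl.channel_weights, g * wave)
    if cfa_waveform is not None and r_peak_times is not None and cfa_gain != 0.0:
        wave, start_ms = cfa_waveform
        if cfa_pattern_weights is None:
            cfa_pattern_weights = cfa_pattern(montage)
        for t in np.atleast_1d(r_peak_times):
            s0 = int(round(t * fs)) + int(round(start_ms * fs / 1000.0))
            if s0 < 0 or s0 + len(wave) > n_samples:
                skipped += 1
                continue
            eeg[:, s0 : s0 + len(wave)] += np.outer(cfa_pattern_weights, cfa_gain * wave)
    if noise_sd > 0:
        eeg += rng.normal(0.0, noise_sd, size=eeg.shape).astype(dtype, copy=False)
    return eeg, skipped


# ---------------------------------------------------------------------------
# Whole-session simulation


@dataclass
class SimulatedSession:
    config: SessionConfig
    timeline: CardiacTimeline
    ecg: EcgSignal
    eeg: Optional[np.ndarray]
    montage: pd.DataFrame
    events: pd.DataFrame
    trials: pd.DataFrame
    ground_truth: dict
    n_skipped_events: int = 0

    @property
    def fs(self) -> float:
        return self.config.fs

    @property
    def channels(self) -> list[str]:
        return list(self.montage["label"])


def _cardiac_offset_ms(times: np.ndarray, timeline: CardiacTimeline) -> np.ndarray:
    idx = timeline.preceding_beat(times)
    out = np.full(len(np.atleast_1d(times)), np.nan)
    ok = idx >= 0
    out[ok] = (np.atleast_1d(times)[ok] - timeline.r_peak_times[idx[ok]]) * 1000.0
    return out


def simulate_session(
    config: SessionConfig | None = None,
    seed: int | None = None,
) -> SimulatedSession:
    """Simulate a complete session: cardiac timeline, scheduled trials with
    staircase-tracked SSDs, a behaving race-model agent, ECG, and (unless
    disabled) multichannel EEG with the injected components.

    The same seed yields a bit-identical session.
    """
    from .task import StaircaseState, plan_trial, update_staircase

    config = config or SessionConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    montage = load_montage(config.montage_id)
    if config.channels is not None:
        montage = subset_montage(montage, list(config.channels))

    lo, hi = config.pre_cue_window
    per_trial = hi + config.go_display + config.feedback_display + config.iti + 1.0
    duration_est = config.n_trials * per_trial + 30.0
    mean_rr_s = 60.0 / config.mean_hr_bpm
    n_beats = int(math.ceil(duration_est / mean_rr_s)) + 50
    timeline = simulate_rr_series(
        config.mean_hr_bpm, config.rmssd_ms, n_beats, rng, start_time=1.0
    )

    staircases = {
        c: StaircaseState(
            ssd_ms=config.staircase_base_ms,
            base_ms=config.staircase_base_ms,
            step_ms=config.staircase_step_ms,
            max_ms=config.staircase_max_ms,
            floor_ms=config.staircase_floor_ms,
            condition=c,
        )
        for c in CONDITIONS
    }

    ev_rows: list[tuple] = []
    tr_rows: list[tuple] = []
    t_cursor = 2.0
    trial_id = 0
    jitter_sd_s = config.trigger_jitter_sd_ms / 1000.0

    for block, condition in enumerate(config.block_order[: config.n_blocks]):
        types = np.array(["go"] * config.go_per_block + ["stop"] * config.stop_per_block)
        types = types[rng.permutation(len(types))]
        params = config.race.for_condition(condition)
        for ttype in types:
            plan = plan_trial(
                timeline, condition, ttype, staircases[condition], config, rng, t_cursor
            )
            responded, rt = sample_race_outcome(
                params, plan.ssd_ms, ttype, rng, config.go_display * 1000.0
            )
            if ttype == "go":
                outcome = "hit" if responded else "omission"
            else:
                outcome = "commission" if responded else "rejection"
                staircases[condition] = update_staircase(staircases[condition], responded)
            cue = plan.go_cue_time_s
            feedback_t = cue + config.go_display
            trial_end = feedback_t + config.feedback_display

            def add(ev_type: str, t: float, out: str = "") -> None:
                ev_rows.append((trial_id, block, condition, ev_type, t, out))

            i0 = np.searchsorted(timeline.r_peak_times, t_cursor)
            i1 = np.searchsorted(timeline.r_peak_times, trial_end)
            for rt_peak in timeline.r_peak_times[i0:i1]:
                add("r_peak", rt_peak)
            for dt in plan.distractor_event_times_s:
                add("distractor_move", dt)
            add("go_cue", cue)
            if ttype == "stop":
                add("stop_signal", cue + plan.ssd_ms / 1000.0)
            if responded:
                add("response", cue + rt / 1000.0)
            add("feedback", feedback_t, outcome)

            tr_rows.append(
                (
                    trial_id, block, condition, ttype, t_cursor, cue,
                    plan.n_pre_cue_beats, plan.extended,
                    plan.ssd_ms if ttype == "stop" else np.nan,
                    responded, rt if responded else np.nan, outcome,
                    feedback_t, trial_end,
                )
            )
            trial_id += 1
            t_cursor = trial_end + config.iti

    events = pd.DataFrame(
        ev_rows,
        columns=["trial_id", "block", "condition", "event_type", "time_s", "outcome"],
    ).sort_values(["time_s", "trial_id"], kind="stable").reset_index(drop=True)
    trials = pd.DataFrame(
        tr_rows,
        columns=[
            "trial_id", "block", "condition", "trial_type", "trial_start_s",
            "go_cue_time_s", "n_pre_cue_beats", "extended", "ssd_ms",
            "responded", "rt_ms", "outcome", "feedback_time_s", "trial_end_s",
        ],
    )

    duration = t_cursor + 2.0
    timeline = timeline.truncate(duration - 0.8)
    events["cardiac_offset_ms"] = _cardiac_offset_ms(events["time_s"].to_numpy(), timeline)

    ecg = synthesize_ecg(
        timeline, config.fs, noise_sd=config.ecg_noise_sd_uv, rng=rng, duration=duration
    )

    ground_truth = template_ground_truth(config)

    eeg = None
    skipped = 0
    if config.render_eeg:
        templates = default_templates(montage, config.template_gains)
        n_samples = int(math.ceil(duration * config.fs))
        dtype = np.float32 if n_samples * len(montage) > 6e7 else np.float64
        eeg, skipped = render_eeg(
            events,
            templates,
            montage,
            config.fs,
            n_samples,
            noise_sd=config.noise_sd_uv,
            rng=rng,
            cfa_waveform=default_cfa_waveform(config.fs),
            r_peak_times=timeline.r_peak_times,
            cfa_gain=config.cfa_gain,
            dtype=dtype,
        )

    return SimulatedSession(
        config=config,
        timeline=timeline,
        ecg=ecg,
        eeg=eeg,
        montage=montage,
        events=events,
        trials=trials,
        ground_truth=ground_truth,
        n_skipped_events=skipped,
    )
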