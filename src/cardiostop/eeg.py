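"""EEG preprocessing, epoching, artifact handling, and ROI amplitudes.

Stages mirror a conventional ERP pipeline: band-limiting (0.1-40 Hz,
zero-phase) and average reference; event-locked segmentation with 100 ms
pre-event baseline correction; +/-100 uV amplitude rejection; cardiac
field artifact (CFA) estimation from phase-classified random triggers and
R-locked subtraction; component decomposition with ECG-coherence ranking
and deletion; and mean-amplitude extraction over channel x time regions of
interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .ecg import code_cardiac_phase
from .simulate import CardiacTimeline, SimulatedSession, default_cfa_waveform, default_templates

__all__ = [
    "preprocess",
    "EpochSet",
    "extract_epochs",
    "reject_epochs",
    "CfaTemplate",
    "estimate_cfa",
    "subtract_cfa",
    "ComponentSet",
    "decompose_session",
    "rank_components_by_ecg_coherence",
    "remove_components",
    "roi_mean_amplitude",
    "ROI_DEFINITIONS",
]

# Channel lists and windows (ms, relative to the locking event) of the
# regions of interest used for condition-effect estimation.
ROI_DEFINITIONS: dict[str, dict] = {
    "hep": {"channels": ["FC1", "FCz", "FC2", "C1", "Cz", "C2"], "window_ms": (300.0, 400.0)},
    "p2": {
        "channels": [
            "F3", "F1", "Fz", "F2", "FC3", "FC1", "FCz", "FC2", "FC4",
            "C3", "C1", "Cz", "C2", "C4", "CPz", "CP1", "CP2",
        ],
        "window_ms": (200.0, 300.0),
    },
    "n2": {"channels": ["AFz", "F1", "Fz", "F2", "FC1", "FCz", "FC2"], "window_ms": (200.0, 300.0)},
    "p3": {"channels": ["C1", "Cz", "C2", "CP1", "CPz", "CP2"], "window_ms": (300.0, 400.0)},
}


def _lowpass_taps(fs: float, lp: float) -> np.ndarray:
    numtaps = int(3.3 * fs / 8.0) | 1  # ~8 Hz transition band
    return sps.firwin(numtaps, lp * 1.1, window="hamming", fs=fs)


def preprocess(
    eeg: np.ndarray, fs: float, hp: float = 0.1, lp: float = 40.0, rereference: bool = True
) -> np.ndarray:
    """Band-limit (hp-lp Hz) and re-reference to the channel average.

    The low-pass is a zero-phase Hamming FIR; the high-pass a zero-phase
    second-order Butterworth (an FIR at 0.1 Hz would need tens of seconds
    of impulse response). After average referencing the channel mean is
    zero at every sample.
    """
    x = np.asarray(eeg, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("eeg must be channels x samples with >= 2 channels")
    if lp is not None:
        taps = _lowpass_taps(fs, lp)
        x = sps.oaconvolve(x, taps[None, :], mode="same", axes=1)
    if hp is not None and hp > 0:
        sos = sps.butter(2, hp, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    if rereference:
        x = x - x.mean(axis=0, keepdims=True)
    return x


def bandlimit_1d(x: np.ndarray, fs: float, hp: float = 0.1, lp: float = 40.0) -> np.ndarray:
    """The preprocessing band-limit applied to a single time course (no
    re-referencing). Filtering is linear, so a rank-1 scalp contribution
    pattern (x) source can be preprocessed by filtering the source alone."""
    x = np.asarray(x, dtype=float)
    if lp is not None:
        x = sps.oaconvolve(x, _lowpass_taps(fs, lp), mode="same")
    if hp is not None and hp > 0:
        sos = sps.butter(2, hp, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    return x


@dataclass
class EpochSet:
    """Epochs x channels x samples with window and baseline metadata."""

    data: np.ndarray
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    fs: float
    channels: list[str]
    event_type: str = ""
    condition: str = ""
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        expected = int(round((self.window_ms[1] - self.window_ms[0]) * self.fs / 1000.0))
        if self.data.shape[2] != expected:
            raise ValueError("sample count inconsistent with window and fs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times (ms relative to the event), half-open window."""
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def crop_ms(self, t0: float, t1: float) -> "EpochSet":
        """Restrict epochs to the [t0, t1) sub-window (ms post event)."""
        j0 = int(round((t0 - self.window_ms[0]) * self.fs / 1000.0))
        j1 = int(round((t1 - self.window_ms[0]) * self.fs / 1000.0))
        if j0 < 0 or j1 > self.data.shape[2] or j1 <= j0:
            raise ValueError("crop window outside epoch support")
        return replace(self, data=self.data[:, :, j0:j1], window_ms=(t0, t1))


def select_first_n_per_trial(
    event_times_s: np.ndarray, trial_ids: np.ndarray, n: int
) -> np.ndarray:
    """Boolean mask keeping the first ``n`` events (by time) of each trial."""
    order = np.argsort(event_times_s, kind="stable")
    keep = np.zeros(len(event_times_s), dtype=bool)
    seen: dict = {}
    for i in order:
        tid = trial_ids[i]
        c = seen.get(tid, 0)
        if c < n:
            keep[i] = True
            seen[tid] = c + 1
    return keep


def extract_epochs(
    eeg: np.ndarray,
    fs: float,
    channels: list[str],
    event_times_s: np.ndarray,
    window_ms: tuple[float, float] = (-100.0, 1000.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    event_type: str = "",
    condition: str = "",
    trial_ids: np.ndarray | None = None,
    first_n_per_trial: int | None = None,
) -> EpochSet:
    """Slice per-event segments and subtract the per-channel baseline mean.

    Windows are half-open ``[start, end)`` in ms relative to the event.
    Events whose window under- or over-runs the recording are dropped and
    counted. ``first_n_per_trial`` restricts to the first qualifying events
    of each trial (used for heartbeat- and movement-locked potentials,
    which are analysed for the first three pre-cue events only).
    """
    eeg = np.asarray(eeg)
    times = np.asarray(event_times_s, dtype=float)
    if first_n_per_trial is not None:
        if trial_ids is None:
            raise ValueError("first_n_per_trial requires trial_ids")
        keep = select_first_n_per_trial(times, np.asarray(trial_ids), first_n_per_trial)
        times = times[keep]
    n_samp = int(round((window_ms[1] - window_ms[0]) * fs / 1000.0))
    off0 = int(round(window_ms[0] * fs / 1000.0))
    b0 = int(round((baseline_ms[0] - window_ms[0]) * fs / 1000.0))
    b1 = int(round((baseline_ms[1] - window_ms[0]) * fs / 1000.0))
    segs, kept_times, dropped = [], [], 0
    for t in times:
        s0 = int(round(t * fs)) + off0
        if s0 < 0 or s0 + n_samp > eeg.shape[1]:
            dropped += 1
            continue
        seg = np.array(eeg[:, s0 : s0 + n_samp], dtype=float)
        if b1 > b0:
            seg -= seg[:, b0:b1].mean(axis=1, keepdims=True)
        segs.append(seg)
        kept_times.append(t)
    data = np.stack(segs) if segs else np.empty((0, eeg.shape[0], n_samp))
    if not segs and len(times):
        warnings.warn(f"no usable events for {event_type or 'epoching'}")
    return EpochSet(
        data=data,
        window_ms=window_ms,
        baseline_ms=baseline_ms,
        fs=fs,
        channels=list(channels),
        event_type=event_type,
        condition=condition,
        event_times_s=np.asarray(kept_times),
        n_dropped=dropped,
    )


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> tuple[EpochSet, float]:
    """Remove epochs in which any sample on any channel exceeds
    +/-threshold. Returns (kept epochs, exclusion rate)."""
    if epochs.n_epochs == 0:
        return epochs, 0.0
    bad = np.any(np.abs(epochs.data) > threshold_uv, axis=(1, 2))
    rate = float(bad.mean())
    kept = replace(
        epochs,
        data=epochs.data[~bad],
        event_times_s=epochs.event_times_s[~bad] if len(epochs.event_times_s) else epochs.event_times_s,
    )
    if kept.n_epochs == 0:
        warnings.warn("all epochs rejected")
    return kept, rate


# ---------------------------------------------------------------------------
# Cardiac field artifact


@dataclass
class CfaTemplate:
    """Per-phase average waveform (channels x samples) around cardiac
    triggers, with the trigger counts that produced it."""

    data: dict[str, np.ndarray]
    counts: dict[str, int]
    window_ms: tuple[float, float]
    fs: float
    align: str = "r_peak"


def estimate_cfa(
    eeg: np.ndarray,
    fs: float,
    timeline: CardiacTimeline,
    n_triggers: int,
    rng: np.random.Generator | int | None = None,
    periods: list[tuple[float, float]] | None = None,
    window_ms: tuple[float, float] = (-1000.0, 2000.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    align: str = "r_peak",
) -> CfaTemplate:
    """Estimate the cardiac field artifact from random triggers.

    Triggers are placed uniformly over the cardiac cycles within
    ``periods`` (default: the whole recording), classified as systole or
    diastole by their position in the cycle, segmented over ``window_ms``,
    baseline-corrected over ``baseline_ms``, and averaged per phase.

    With ``align="r_peak"`` (default) segments are anchored at the R-peak
    preceding each trigger, so the per-phase average is an estimate of the
    R-locked artifact and can be subtracted beat-by-beat. With
    ``align="trigger"`` segments are anchored at the triggers themselves.
    """
    if align not in ("r_peak", "trigger"):
        raise ValueError("align must be 'r_peak' or 'trigger'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eeg = np.asarray(eeg)
    n_ch, n_total = eeg.shape
    if periods is None:
        periods = [(float(timeline.r_peak_times[0]), float(timeline.r_peak_times[-1]))]
    lengths = np.array([max(b - a, 0.0) for a, b in periods], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("periods have zero total length")
    n_samp = int(round((window_ms[1] - window_ms[0]) * fs / 1000.0))
    off0 = int(round(window_ms[0] * fs / 1000.0))
    b0 = int(round((baseline_ms[0] - window_ms[0]) * fs / 1000.0))
    b1 = int(round((baseline_ms[1] - window_ms[0]) * fs / 1000.0))

    which = rng.choice(len(periods), size=n_triggers, p=lengths / lengths.sum())
    u = rng.random(n_triggers)
    triggers = np.array([periods[w][0] + u[k] * (periods[w][1] - periods[w][0]) for k, w in enumerate(which)])

    phases = code_cardiac_phase(triggers, timeline)
    acc = {p: np.zeros((n_ch, n_samp)) for p in ("systole", "diastole")}
    counts = {p: 0 for p in ("systole", "diastole")}
    beat_idx = timeline.preceding_beat(triggers)
    for t, ph, bi in zip(triggers, phases, beat_idx):
        if ph not in acc:
            continue
        anchor = t if align == "trigger" else float(timeline.r_peak_times[bi])
        s0 = int(round(anchor * fs)) + off0
        if s0 < 0 or s0 + n_samp > n_total:
            continue
        seg = np.array(eeg[:, s0 : s0 + n_samp], dtype=float)
        if b1 > b0:
            seg -= seg[:, b0:b1].mean(axis=1, keepdims=True)
        acc[ph] += seg
        counts[ph] += 1
    for p in acc:
        if counts[p] < 10:
            warnings.warn(f"only {counts[p]} {p} triggers for CFA estimation")
        if counts[p] > 0:
            acc[p] /= counts[p]
    return CfaTemplate(data=acc, counts=counts, window_ms=window_ms, fs=fs, align=align)


def subtract_cfa(
    eeg: np.ndarray,
    fs: float,
    template: CfaTemplate,
    timeline: CardiacTimeline,
    phase: str = "systole",
    support_ms: tuple[float, float] = (-50.0, 450.0),
) -> np.ndarray:
    """Subtract the phase template time-locked to each R-peak.

    Only the template's artifact-bearing support (default -50 to 450 ms
    around R, the extent of the QRS-plus-T field, clipped per beat to the
    local RR interval) is subtracted, so
    neighbouring beats are each corrected by their own subtraction. The
    same template is meant to be applied identically across all
    experimental conditions.
    """
    if template.align != "r_peak":
        raise ValueError("beat-locked subtraction requires an R-peak-aligned template")
    tpl = template.data.get(phase)
    if tpl is None or template.counts.get(phase, 0) == 0:
        raise ValueError(f"template has no data for phase {phase!r}")
    if tpl.shape[0] != eeg.shape[0]:
        raise ValueError("template channel count does not match data")
    out = np.array(eeg, dtype=float)
    w0 = template.window_ms[0]
    rr = timeline.rr_intervals
    for i, r in enumerate(timeline.r_peak_times):
        rr_next = rr[i] if i < len(rr) else (rr[-1] if len(rr) else 1000.0)
        lo = support_ms[0]
        hi = min(support_ms[1], 0.95 * rr_next)
        k0 = int(round((lo - w0) * fs / 1000.0))
        k1 = int(round((hi - w0) * fs / 1000.0))
        k0, k1 = max(k0, 0), min(k1, tpl.shape[1])
        if k1 <= k0:
            continue
        s0 = int(round(r * fs)) + int(round(lo * fs / 1000.0))
        seg0, seg1 = max(s0, 0), min(s0 + (k1 - k0), out.shape[1])
        if seg1 <= seg0:
            continue
        out[:, seg0:seg1] -= tpl[:, k0 + (seg0 - s0) : k0 + (seg1 - s0)]
    return out


def r_locked_power(
    eeg: np.ndarray, fs: float, timeline: CardiacTimeline, window_ms: tuple[float, float] = (-50.0, 450.0)
) -> float:
    """Mean-square amplitude of the R-locked average waveform; the metric
    the CFA correction is meant to suppress."""
    ep = extract_epochs(
        eeg, fs, [str(i) for i in range(eeg.shape[0])],
        timeline.r_peak_times, window_ms=window_ms, baseline_ms=(0.0, 0.0),
    )
    if ep.n_epochs == 0:
        return float("nan")
    return float(np.mean(ep.average() ** 2))


# ---------------------------------------------------------------------------
# Component decomposition and ECG-coherence ranking


@dataclass
class ComponentSet:
    """Linear decomposition: data = mixing @ sources + residual."""

    sources: np.ndarray  # components x samples
    mixing: np.ndarray  # channels x components
    names: list[str]
    residual: np.ndarray  # channels x samples
    data: Optional[np.ndarray] = None  # original scalp data, if retained
    coherence: Optional[np.ndarray] = None
    order: Optional[np.ndarray] = None  # descending-coherence component indices

    def reconstruct(self, drop: list[int] | np.ndarray | None = None) -> np.ndarray:
        """Scalp data without the dropped components (all kept: exact
        reconstruction of the input)."""
        x = self.data if self.data is not None else self.mixing @ self.sources + self.residual
        if drop is not None and len(drop):
            drop = np.asarray(drop, dtype=int)
            if drop.min() < 0 or drop.max() >= self.mixing.shape[1]:
                raise IndexError("component index out of range")
            x = x - self.mixing[:, drop] @ self.sources[drop]
        elif self.data is not None:
            x = np.array(x)
        return x


def decompose_session(
    session: SimulatedSession, eeg: np.ndarray | None = None
) -> ComponentSet:
    """Decompose session EEG onto the simulator's known sources.

    Each injected template (and the cardiac field artifact) contributes one
    component whose spatial map is its channel-weight pattern and whose
    time course is the gain-weighted sum of its event-locked waveforms.
    The residual holds everything else (noise). This exercises component
    ranking/deletion without re-deriving a blind decomposition.
    """
    if eeg is None:
        eeg = session.eeg
    if eeg is None:
        raise ValueError("session has no rendered EEG")
    fs = session.fs
    n_samples = eeg.shape[1]
    templates = default_templates(session.montage, session.config.template_gains)
    names, cols, srcs = [], [], []
    for name, tpl in templates.items():
        wave = tpl.waveform(fs)
        src = np.zeros(n_samples)
        sel = session.events[session.events["event_type"] == tpl.event_type]
        if tpl.feedback_kind is not None:
            sel = sel[sel["outcome"] == tpl.feedback_kind]
        any_event = False
        for t, cond in zip(sel["time_s"].to_numpy(), sel["condition"].to_numpy()):
            g = tpl.gain(cond)
            if g == 0.0:
                continue
            s0 = int(round(t * fs)) + int(round(tpl.window_ms[0] * fs / 1000.0))
            if s0 < 0 or s0 + len(wave) > n_samples:
                continue
            src[s0 : s0 + len(wave)] += g * wave
            any_event = True
        if any_event:
            names.append(name)
            cols.append(tpl.channel_weights)
            srcs.append(src)
    if session.config.cfa_gain != 0.0:
        from .simulate import cfa_pattern as _cfa_pattern

        wave, start_ms = default_cfa_waveform(fs)
        src = np.zeros(n_samples)
        for t in session.timeline.r_peak_times:
            s0 = int(round(t * fs)) + int(round(start_ms * fs / 1000.0))
            if s0 < 0 or s0 + len(wave) > n_samples:
                continue
            src[s0 : s0 + len(wave)] += session.config.cfa_gain * wave
        names.append("cfa")
        cols.append(_cfa_pattern(session.montage))
        srcs.append(src)
    mixing = np.column_stack(cols) if cols else np.empty((eeg.shape[0], 0))
    sources = np.vstack(srcs) if srcs else np.empty((0, n_samples))
    data = np.asarray(eeg, dtype=float)
    residual = data - mixing @ sources
    return ComponentSet(
        sources=sources, mixing=mixing, names=names, residual=residual, data=data
    )


def decompose_ica(
    eeg: np.ndarray,
    n_components: int,
    rng: np.random.Generator | int | None = None,
) -> ComponentSet:
    """Blind decomposition hook (FastICA).

    Alternative to :func:`decompose_session` when no ground-truth mixing
    is available. The residual holds the part of the data outside the
    retained component subspace, so reconstruction with no removal is
    still exact.
    """
    from sklearn.decomposition import FastICA

    seed = rng if isinstance(rng, int) else None
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    data = np.asarray(eeg, dtype=float)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=500)
    sources = ica.fit_transform(data.T).T
    mixing = ica.mixing_
    mean = ica.mean_[:, None]
    residual = data - (mixing @ sources + mean) + mean  # = data - mixing@sources
    return ComponentSet(
        sources=sources,
        mixing=mixing,
        names=[f"ica{j}" for j in range(sources.shape[0])],
        residual=residual,
        data=data,
    )


def rank_components_by_ecg_coherence(
    components: ComponentSet,
    ecg: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (0.5, 10.0),
    method: str = "coherence",
    top_n: int | None = None,
) -> ComponentSet:
    """Score each component's symmetry with the ECG and rank descending.

    ``method="coherence"``: magnitude-squared coherence (Welch) averaged
    over ``band_hz``. ``method="correlation"``: absolute Pearson
    correlation of the time courses. Constant components have an undefined
    score and are ranked last. ``top_n`` truncates the rank order.
    """
    ecg = np.asarray(ecg, dtype=float)
    k, n = components.sources.shape
    m = min(n, len(ecg))
    scores = np.empty(k)
    for i in range(k):
        src = components.sources[i, :m]
        if np.ptp(src) == 0:
            scores[i] = -1.0  # undefined: flagged below every real score
            continue
        if method == "coherence":
            nperseg = min(m, int(8 * fs))
            with np.errstate(divide="ignore", invalid="ignore"):
                f, cxy = sps.coherence(src, ecg[:m], fs=fs, nperseg=nperseg)
            sel = (f >= band_hz[0]) & (f <= band_hz[1]) & np.isfinite(cxy)
            scores[i] = float(np.mean(cxy[sel])) if sel.any() else -1.0
        elif method == "correlation":
            scores[i] = float(abs(np.corrcoef(src, ecg[:m])[0, 1]))
        else:
            raise ValueError("method must be 'coherence' or 'correlation'")
    order = np.argsort(-scores, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    return replace(components, coherence=scores, order=order)


def remove_components(
    components: ComponentSet, indices: list[int] | np.ndarray
) -> np.ndarray:
    """Reconstruct the scalp data without the selected components.

    Removing none returns the input exactly; removing all leaves only the
    residual (with a warning)."""
    indices = np.asarray(indices, dtype=int)
    if len(indices) == components.mixing.shape[1] and components.mixing.shape[1] > 0:
        warnings.warn("removing every component: only the residual remains")
    return components.reconstruct(drop=indices)


def roi_mean_amplitude(
    epochs: EpochSet, channels: list[str], window_ms: tuple[float, float]
) -> np.ndarray:
    """Mean amplitude (uV) over the ROI channels x window samples, one
    value per epoch."""
    missing = [c for c in channels if c not in epochs.channels]
    if missing:
        raise KeyError(f"channels not in epochs: {missing}")
    ch_idx = [epochs.channels.index(c) for c in channels]
    j0 = int(round((window_ms[0] - epochs.window_ms[0]) * epochs.fs / 1000.0))
    j1 = int(round((window_ms[1] - epochs.window_ms[0]) * epochs.fs / 1000.0))
    if j0 < 0 or j1 > epochs.data.shape[2] or j1 <= j0:
        raise ValueError("ROI window outside epoch support")
    return epochs.data[:, ch_idx, j0:j1].mean(axis=(1, 2))
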