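"""End-to-end analysis chains over simulated sessions.

Glue shared by the CLI, the tests, and the acceptance checks: component-
specific epoch selection (which events, which window, first-N rules),
per-subject condition averages, ROI amplitude tables, and group-level
cluster contrasts between the systole- and diastole-coupled conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg import (
    ROI_DEFINITIONS,
    ComponentSet,
    EpochSet,
    bandlimit_1d,
    decompose_session,
    estimate_cfa,
    extract_epochs,
    preprocess,
    rank_components_by_ecg_coherence,
    reject_epochs,
    roi_mean_amplitude,
    subtract_cfa,
)
from .montage import gaussian_scalp_pattern
from .simulate import SimulatedSession, cfa_pattern
from .stats import AdjacencyGraph, ClusterResult, cluster_permutation_test

# Locking event, epoch window, first-N-per-trial rule, and trial/outcome
# filters for each analysed component.
COMPONENT_EPOCHING: dict[str, dict] = {
    "hep": {"event_type": "r_peak", "window_ms": (-100.0, 1000.0), "first_n": 3},
    "p2": {"event_type": "distractor_move", "window_ms": (-100.0, 1000.0), "first_n": 3},
    "go": {"event_type": "go_cue", "window_ms": (-100.0, 1000.0), "trial_type": "go"},
    "n2": {"event_type": "stop_signal", "window_ms": (-100.0, 750.0)},
    "p3": {"event_type": "feedback", "window_ms": (-100.0, 1000.0), "outcome": "commission"},
}

BASELINE_MS = (-100.0, 0.0)


def component_events(
    session: SimulatedSession, component: str, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Times and trial ids of the events a component is locked to."""
    spec = COMPONENT_EPOCHING[component]
    ev = session.events
    sel = ev[(ev["event_type"] == spec["event_type"]) & (ev["condition"] == condition)]
    if "outcome" in spec:
        sel = sel[sel["outcome"] == spec["outcome"]]
    if "trial_type" in spec:
        ttype = session.trials.set_index("trial_id")["trial_type"]
        sel = sel[sel["trial_id"].map(ttype) == spec["trial_type"]]
    if "first_n" in spec:
        # pre-cue events only, then the first N per trial
        cue = session.trials.set_index("trial_id")["go_cue_time_s"]
        sel = sel[sel["time_s"] < sel["trial_id"].map(cue)]
    return sel["time_s"].to_numpy(), sel["trial_id"].to_numpy()


def component_epochs(
    session: SimulatedSession,
    component: str,
    condition: str,
    eeg: np.ndarray | None = None,
    reject_uv: float | None = 100.0,
) -> EpochSet:
    """Epochs for one component in one condition, baseline-corrected and
    (by default) amplitude-rejected at +/-100 uV."""
    spec = COMPONENT_EPOCHING[component]
    times, tids = component_events(session, component, condition)
    ep = extract_epochs(
        session.eeg if eeg is None else eeg,
        session.fs,
        session.channels,
        times,
        window_ms=spec["window_ms"],
        baseline_ms=BASELINE_MS,
        event_type=spec["event_type"],
        condition=condition,
        trial_ids=tids,
        first_n_per_trial=spec.get("first_n"),
    )
    if reject_uv is not None:
        ep, _ = reject_epochs(ep, reject_uv)
    return ep


@dataclass
class SubjectErp:
    """Per-condition average waveforms and ROI epoch amplitudes for one
    subject."""

    averages: dict[str, dict[str, np.ndarray]]  # component -> condition -> ch x samp
    roi_epoch_means: pd.DataFrame  # component, condition, n_epochs, roi_mean_uv
    channels: list[str]
    fs: float


def identify_components(
    components: ComponentSet, montage: pd.DataFrame
) -> list[str]:
    """Label each component by the spatial template its mixing weights
    match best (cosine similarity against the configurable component
    pattern bank); the reproducible stand-in for identification by visual
    topography inspection."""
    bank = {
        "hep": gaussian_scalp_pattern(montage, ["FCz", "Cz"], 20.0),
        "p2": gaussian_scalp_pattern(montage, ["FCz"], 30.0),
        "go": gaussian_scalp_pattern(montage, ["Cz"], 25.0),
        "n2": gaussian_scalp_pattern(montage, ["Fz", "FCz"], 20.0),
        "p3": gaussian_scalp_pattern(montage, ["Cz", "CPz"], 20.0),
        "cfa": cfa_pattern(montage),
    }
    labels = []
    for j in range(components.mixing.shape[1]):
        col = components.mixing[:, j]
        nc = np.linalg.norm(col)
        best, best_sim = "unknown", -np.inf
        for name, pat in bank.items():
            sim = abs(col @ pat) / (nc * np.linalg.norm(pat) + 1e-30)
            if sim > best_sim:
                best, best_sim = name, sim
        labels.append(best)
    return labels


def corrected_traces(
    session: SimulatedSession,
    rng: np.random.Generator | int | None = None,
    do_component_removal: bool = True,
    do_cfa: bool = True,
    n_cfa_triggers: int = 300,
    coherence_top_n: int = 30,
    coherence_method: str = "coherence",
) -> dict[str, np.ndarray | dict[str, np.ndarray]]:
    """Build the analysis traces the paper's control procedures prescribe.

    * ``default``: preprocessed EEG (for go/stop/feedback potentials).
    * ``hep``: movement-locked (P2-like) components, found among the most
      ECG-coherent components by spatial template match, deleted before
      preprocessing — the heartbeat-locked trace.
    * ``p2``: heartbeat-locked (HEP-like) components deleted, then the
      phase-appropriate cardiac-field-artifact template (estimated from
      random triggers over the distractor-encounter period) subtracted
      beat-by-beat — one corrected trace per condition.
    """
    if session.eeg is None:
        raise ValueError("session has no rendered EEG")
    fs = session.fs
    raw = session.eeg
    traces: dict = {}
    traces["default"] = preprocess(raw, fs)

    def _minus_components(pre: np.ndarray, comp: ComponentSet, idx: list[int]) -> np.ndarray:
        # preprocessing is linear: subtract each removed component's
        # preprocessed rank-1 contribution (demeaned pattern x filtered
        # source) from the preprocessed trace
        if not idx:
            return pre
        out = np.array(pre)
        for j in idx:
            pat = comp.mixing[:, j] - comp.mixing[:, j].mean()
            out -= np.outer(pat, bandlimit_1d(comp.sources[j], fs))
        return out

    if do_component_removal:
        comp = decompose_session(session)
        ranked = rank_components_by_ecg_coherence(
            comp, session.ecg.samples, fs, top_n=coherence_top_n,
            method=coherence_method,
        )
        labels = identify_components(comp, session.montage)
        p2_like = [i for i in ranked.order if labels[i] == "p2"]
        hep_like = [i for i in ranked.order if labels[i] == "hep"]
        traces["hep"] = _minus_components(traces["default"], comp, p2_like)
        pre_p2 = _minus_components(traces["default"], comp, hep_like)
    else:
        traces["hep"] = traces["default"]
        pre_p2 = traces["default"]
    if do_cfa:
        periods = [
            (float(t0), float(t1))
            for t0, t1 in zip(
                session.trials["trial_start_s"], session.trials["go_cue_time_s"]
            )
        ]
        tpl = estimate_cfa(
            pre_p2, fs, session.timeline, n_cfa_triggers, rng=rng, periods=periods
        )
        traces["p2"] = {
            cond: subtract_cfa(pre_p2, fs, tpl, session.timeline, phase=phase)
            for cond, phase in (
                ("systole", "systole"), ("diastole", "diastole"), ("none", "diastole"),
            )
        }
    else:
        traces["p2"] = pre_p2
    return traces


def analyze_subject_erps(
    session: SimulatedSession,
    components: tuple[str, ...] = ("hep", "p2", "n2", "p3"),
    conditions: tuple[str, ...] = ("systole", "diastole", "none"),
    eeg: np.ndarray | None = None,
    do_preprocess: bool = True,
    rng: np.random.Generator | int | None = None,
    correct: bool = False,
    correct_opts: dict | None = None,
) -> SubjectErp:
    """Compute component x condition average waveforms and ROI means.

    With ``correct=True`` the paper-style control corrections are applied:
    component deletion for the HEP/P2 traces and CFA subtraction for the
    P2 trace (see :func:`corrected_traces`). Otherwise a single trace
    (``eeg`` if given, else the session EEG, optionally preprocessed) is
    used for every component.
    """
    if correct:
        traces = corrected_traces(session, rng=rng, **(correct_opts or {}))
    else:
        x = session.eeg if eeg is None else eeg
        if x is None:
            raise ValueError("session has no rendered EEG")
        if do_preprocess:
            x = preprocess(x, session.fs)
        traces = {"default": x, "hep": x, "p2": x}
    averages: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for comp in components:
        averages[comp] = {}
        roi = ROI_DEFINITIONS.get(comp)
        for cond in conditions:
            if comp == "p2" and cond == "none":
                continue  # no distractor events in the control condition
            trace = traces.get(comp, traces["default"])
            if isinstance(trace, dict):
                trace = trace[cond]
            times, _ = component_events(session, comp, cond)
            if len(times) == 0:
                continue
            ep = component_epochs(session, comp, cond, eeg=trace)
            if ep.n_epochs == 0:
                continue
            averages[comp][cond] = ep.average()
            if roi is not None and all(c in ep.channels for c in roi["channels"]):
                vals = roi_mean_amplitude(ep, roi["channels"], roi["window_ms"])
                rows.append((comp, cond, ep.n_epochs, float(vals.mean())))
    return SubjectErp(
        averages=averages,
        roi_epoch_means=pd.DataFrame(
            rows, columns=["component", "condition", "n_epochs", "roi_mean_uv"]
        ),
        channels=session.channels,
        fs=session.fs,
    )


def group_cluster_contrast(
    subject_erps: list[SubjectErp],
    component: str,
    adjacency: AdjacencyGraph,
    cond_a: str = "systole",
    cond_b: str = "diastole",
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    test_window_ms: tuple[float, float] | None = None,
) -> ClusterResult:
    """Cluster permutation test of cond_a vs cond_b subject averages.

    The test runs over the post-event portion of the epoch (0 ms to the
    window end) unless ``test_window_ms`` overrides it.
    """
    spec = COMPONENT_EPOCHING[component]
    w0, w1 = test_window_ms if test_window_ms is not None else (0.0, spec["window_ms"][1])
    fs = subject_erps[0].fs
    win = spec["window_ms"]
    j0 = int(round((w0 - win[0]) * fs / 1000.0))
    j1 = int(round((w1 - win[0]) * fs / 1000.0))
    a, b = [], []
    for s in subject_erps:
        if cond_a not in s.averages.get(component, {}) or cond_b not in s.averages.get(component, {}):
            continue
        a.append(s.averages[component][cond_a][:, j0:j1])
        b.append(s.averages[component][cond_b][:, j0:j1])
    if len(a) < 2:
        raise ValueError(f"need >= 2 subjects with both conditions for {component}")
    return cluster_permutation_test(
        np.stack(a), np.stack(b), adjacency, n_permutations=n_permutations, rng=rng
    )


def cluster_overlaps_roi(
    result: ClusterResult,
    component: str,
    channels: list[str],
    fs: float,
    test_window_start_ms: float = 0.0,
) -> bool:
    """True if any significant cluster touches the component's ROI channels
    within its expected latency window."""
    roi = ROI_DEFINITIONS[component]
    roi_idx = {channels.index(c) for c in roi["channels"] if c in channels}
    w0, w1 = roi["window_ms"]
    s0 = int(round((w0 - test_window_start_ms) * fs / 1000.0))
    s1 = int(round((w1 - test_window_start_ms) * fs / 1000.0))
    for cl in result.significant_clusters:
        ch = cl.members[:, 0]
        sm = cl.members[:, 1]
        if np.any(np.isin(ch, list(roi_idx)) & (sm >= s0) & (sm < s1)):
            return True
    return False
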