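"""Trial scheduling, staircase tracking, and cardiac timing audit.

The staircase keeps stop-trial success near 50%: a correctly withheld
response adds one step (50 ms) to the stop-signal delay, a commission
subtracts one step, with the delay bounded in [floor, 750] ms. The trial
planner places the go-cue uniformly 2.9-4.5 s into the trial subject to at
least three preceding heartbeats, and couples one distractor movement onset
to each pre-cue heartbeat at the condition's cardiac offset plus trigger
latency jitter. The timing audit recomputes each coupled event's realized
offset against the offline R-peaks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .config import SessionConfig
    from .simulate import CardiacTimeline


class SchedulingError(RuntimeError):
    """Raised when the cardiac timeline cannot host the requested trial."""


@dataclass(frozen=True)
class StaircaseState:
    ssd_ms: float
    base_ms: float = 200.0
    step_ms: float = 50.0
    max_ms: float = 750.0
    floor_ms: float = 50.0
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.floor_ms <= self.ssd_ms <= self.max_ms:
            raise ValueError("ssd_ms must lie in [floor_ms, max_ms]")


def update_staircase(state: StaircaseState, responded_on_stop: bool) -> StaircaseState:
    """One staircase transition. A withheld response (stop success) raises
    the SSD by one step, capped at the maximum; a response lowers it by one
    step, floored."""
    if responded_on_stop:
        new = max(state.ssd_ms - state.step_ms, state.floor_ms)
    else:
        new = min(state.ssd_ms + state.step_ms, state.max_ms)
    return dataclasses.replace(state, ssd_ms=new)


@dataclass
class TrialPlan:
    trial_type: str
    condition: str
    trial_start_s: float
    go_cue_time_s: float
    distractor_event_times_s: np.ndarray
    ssd_ms: float | None
    feedback_time_s: float
    n_pre_cue_beats: int
    extended: bool = False


def plan_trial(
    timeline: "CardiacTimeline",
    condition: str,
    trial_type: str,
    staircase: StaircaseState,
    config: "SessionConfig",
    rng: np.random.Generator,
    trial_start_s: float = 0.0,
    max_retries: int = 100,
) -> TrialPlan:
    """Place the go-cue and cardiac-coupled distractor events for one trial.

    The cue delay is drawn uniformly from the configured pre-cue window and
    redrawn (bounded retries) until at least the minimum number of
    heartbeats precedes the cue. If no draw satisfies the constraint the
    window is extended to 50 ms past the minimum-count beat and the trial
    is flagged ``extended``.
    """
    r = timeline.r_peak_times
    lo, hi = config.pre_cue_window
    i0 = int(np.searchsorted(r, trial_start_s))
    need = config.min_heartbeats_pre_cue
    if i0 + need > len(r):
        raise SchedulingError("cardiac timeline too short for trial")

    extended = False
    cue_delay = None
    for _ in range(max_retries):
        d = rng.uniform(lo, hi)
        n_beats = int(np.searchsorted(r, trial_start_s + d) - i0)
        if n_beats >= need:
            cue_delay = d
            break
    if cue_delay is None:
        # Slow heart: stretch the display until the minimum beat count.
        cue_delay = (r[i0 + need - 1] + 0.05) - trial_start_s
        extended = True
    cue = trial_start_s + cue_delay
    n_pre = int(np.searchsorted(r, cue) - i0)

    offset_ms = config.coupling_offset_ms(condition)
    if offset_ms is None:
        distractors = np.empty(0)
    else:
        beats = r[i0 : i0 + n_pre]
        jitter = rng.normal(0.0, config.trigger_jitter_sd_ms / 1000.0, size=len(beats))
        distractors = beats + offset_ms / 1000.0 + jitter

    ssd = staircase.ssd_ms if trial_type == "stop" else None
    feedback = cue + config.go_display
    return TrialPlan(
        trial_type=trial_type,
        condition=condition,
        trial_start_s=trial_start_s,
        go_cue_time_s=cue,
        distractor_event_times_s=distractors,
        ssd_ms=ssd,
        feedback_time_s=feedback,
        n_pre_cue_beats=n_pre,
        extended=extended,
    )


def nearest_r_offset_ms(
    times: np.ndarray, timeline: "CardiacTimeline", intended_ms: float
) -> np.ndarray:
    """Signed offset of each event from the R-peak that best matches the
    intended coupling (minimizing |offset - intended|).

    Events jittered slightly before their coupling R-peak are thereby
    measured as small negative deviations rather than wrapping to nearly a
    full RR interval.
    """
    r = timeline.r_peak_times
    times = np.atleast_1d(times)
    out = np.empty(len(times))
    for k, t in enumerate(times):
        i = int(np.searchsorted(r, t - intended_ms / 1000.0))
        cand = r[max(i - 2, 0) : i + 2]
        offs = (t - cand) * 1000.0
        out[k] = offs[np.argmin(np.abs(offs - intended_ms))]
    return out


def evaluate_timing_precision(
    events: pd.DataFrame,
    timeline: "CardiacTimeline",
    trials: pd.DataFrame,
    intended_ms: dict[str, float] | None = None,
    within_ms: float = 200.0,
    bin_ms: float = 50.0,
) -> pd.DataFrame:
    """Audit realized cardiac timing of coupled distractor events.

    Per condition x trial type: mean and SD of the realized offset from the
    (nearest-matching) R-peak, the fraction of events within ``within_ms``
    of the intended offset, and a 50 ms-bin histogram of realized offsets.
    Returns a DataFrame with one row per (condition, trial_type); the
    histogram (counts, edges) is stored in the ``histogram`` column.
    """
    if intended_ms is None:
        intended_ms = {"systole": 290.0, "diastole": 0.0}
    moves = events[events["event_type"] == "distractor_move"]
    if moves.empty:
        return pd.DataFrame(
            columns=[
                "condition", "trial_type", "n_events", "mean_offset_ms",
                "sd_offset_ms", "frac_within_200ms", "histogram",
            ]
        ).assign(empty=True)
    ttype = trials.set_index("trial_id")["trial_type"]
    moves = moves.assign(trial_type=moves["trial_id"].map(ttype))
    rows = []
    for (cond, tt), grp in moves.groupby(["condition", "trial_type"], sort=True):
        target = intended_ms.get(cond)
        if target is None:
            continue
        offs = nearest_r_offset_ms(grp["time_s"].to_numpy(), timeline, target)
        dev = offs - target
        lo = np.floor(offs.min() / bin_ms) * bin_ms
        hi = np.ceil(offs.max() / bin_ms) * bin_ms
        edges = np.arange(lo, hi + bin_ms, bin_ms)
        counts, edges = np.histogram(offs, bins=edges)
        rows.append(
            (
                cond, tt, len(offs), float(offs.mean()), float(offs.std(ddof=0)),
                float(np.mean(np.abs(dev) <= within_ms)), (counts, edges),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "trial_type", "n_events", "mean_offset_ms",
            "sd_offset_ms", "frac_within_200ms", "histogram",
        ],
    )


def run_closed_loop(
    params,
    n_stop: int,
    staircase: StaircaseState | None = None,
    rng: np.random.Generator | int | None = None,
    n_go_between: int = 2,
    go_display_ms: float = 1500.0,
) -> pd.DataFrame:
    """Run the staircase against the race-model agent.

    Simulates ``n_stop`` stop trials, each preceded by ``n_go_between`` go
    trials (mirroring the 2:1 go:stop ratio of the task), with the SSD
    tracked by the staircase. Returns the trial table (go and stop trials,
    with SSDs, responses and RTs) for behavioral estimation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    st = staircase or StaircaseState(ssd_ms=200.0)

    # The go process is independent of the SSD, so all finishing times can
    # be drawn up front; only the staircase itself is sequential.
    n_go = n_stop * n_go_between
    gf_stop = rng.normal(params.go_mu, params.go_sigma, n_stop) + rng.exponential(
        params.go_tau, n_stop
    )
    omit_stop = rng.random(n_stop) < params.omission_rate
    ssrt = np.full(n_stop, params.ssrt_true)
    if params.ssrt_sd > 0:
        ssrt += rng.normal(0.0, params.ssrt_sd, n_stop)
    ssds = np.empty(n_stop)
    responded_stop = np.empty(n_stop, dtype=bool)
    for i in range(n_stop):
        ssds[i] = st.ssd_ms
        responded_stop[i] = (
            (not omit_stop[i])
            and gf_stop[i] < st.ssd_ms + ssrt[i]
            and gf_stop[i] <= go_display_ms
        )
        st = update_staircase(st, bool(responded_stop[i]))
    stop_df = pd.DataFrame(
        {
            "trial_type": "stop",
            "ssd_ms": ssds,
            "responded": responded_stop,
            "rt_ms": np.where(responded_stop, gf_stop, np.nan),
        }
    )
    if n_go:
        gf_go = rng.normal(params.go_mu, params.go_sigma, n_go) + rng.exponential(
            params.go_tau, n_go
        )
        responded_go = (rng.random(n_go) >= params.omission_rate) & (gf_go <= go_display_ms)
        go_df = pd.DataFrame(
            {
                "trial_type": "go",
                "ssd_ms": np.nan,
                "responded": responded_go,
                "rt_ms": np.where(responded_go, gf_go, np.nan),
            }
        )
        return pd.concat([go_df, stop_df], ignore_index=True)
    return stop_df
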