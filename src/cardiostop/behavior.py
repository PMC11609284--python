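"""Behavioral endpoints: accuracy, median RT/SSD, and integration-method SSRT.

The stop-signal reaction time (SSRT) is the latent latency of the stop
process in the independent race model. The integration method estimates it
from three observables: the go-RT distribution, the probability of
responding on stop trials, and the central stop-signal delay. The n go RTs
are rank-ordered, the RT at rank ceil(n * p(respond|stop)) is taken as the
point where the stop process finishes, and the SSD is subtracted from it.
Omitted go trials are, by default, assigned the maximum observed RT before
rank-ordering so that omissions do not deflate the distribution.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "estimate_ssrt_integration",
    "median_go_rt",
    "median_ssd",
    "summarize_accuracy",
    "summarize_behavior",
]


def estimate_ssrt_integration(
    go_rts_ms: np.ndarray,
    p_respond: float,
    ssd_central_ms: float,
    n_go_omissions: int = 0,
    omission_correction: str = "max_rt",
) -> float:
    """Integration-method SSRT.

    Parameters
    ----------
    go_rts_ms : observed go reaction times (responses only).
    p_respond : probability of responding on stop trials, in (0, 1].
    ssd_central_ms : central stop-signal delay (typically the median SSD
        from the staircase).
    n_go_omissions : number of go trials without a response; with
        ``omission_correction="max_rt"`` each is assigned the maximum
        observed RT before rank-ordering, with ``"exclude"`` they are
        ignored.

    Returns NaN (flagged missing) if ``p_respond`` is 0 or no go RTs exist.
    """
    rts = np.asarray(go_rts_ms, dtype=float)
    rts = rts[np.isfinite(rts)]
    if len(rts) == 0 or not np.isfinite(p_respond) or p_respond <= 0.0:
        return float("nan")
    if p_respond > 1.0:
        raise ValueError("p_respond must lie in (0, 1]")
    if omission_correction == "max_rt" and n_go_omissions > 0:
        rts = np.concatenate([rts, np.full(n_go_omissions, rts.max())])
    elif omission_correction not in ("max_rt", "exclude"):
        raise ValueError(f"unknown omission_correction: {omission_correction!r}")
    srt = np.sort(rts)
    n = len(srt)
    k = min(max(math.ceil(n * p_respond), 1), n)
    return float(srt[k - 1] - ssd_central_ms)


def median_go_rt(trials: pd.DataFrame) -> float:
    """Sample median of go-trial RTs (mean of the middle two for even n)."""
    rts = trials.loc[trials["trial_type"] == "go", "rt_ms"].dropna()
    if rts.empty:
        return float("nan")
    return float(rts.median())


def median_ssd(stop_trials: pd.DataFrame) -> float:
    ssds = stop_trials.loc[stop_trials["trial_type"] == "stop", "ssd_ms"].dropna()
    if ssds.empty:
        return float("nan")
    return float(ssds.median())


def summarize_accuracy(trials: pd.DataFrame, by: str | None = "condition") -> pd.DataFrame:
    """Per-condition accuracy percentages and p(respond | stop)."""
    if by is None:
        groups = [("all", trials)]
    else:
        groups = list(trials.groupby(by, sort=True))
    rows = []
    for cond, grp in groups:
        go = grp[grp["trial_type"] == "go"]
        stop = grp[grp["trial_type"] == "stop"]
        if go.empty and stop.empty:
            warnings.warn(f"condition {cond!r} has no trials; omitted")
            continue
        n_go, n_stop = len(go), len(stop)
        go_hits = int(go["responded"].sum())
        stop_resp = int(stop["responded"].sum())
        rows.append(
            {
                "condition": cond,
                "n_go": n_go,
                "n_stop": n_stop,
                "go_hit_pct": 100.0 * go_hits / n_go if n_go else np.nan,
                "go_omission_pct": 100.0 * (n_go - go_hits) / n_go if n_go else np.nan,
                "stop_commission_pct": 100.0 * stop_resp / n_stop if n_stop else np.nan,
                "p_respond_stop": stop_resp / n_stop if n_stop else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_behavior(
    trials: pd.DataFrame,
    ssd_central: str = "median",
    omission_correction: str = "max_rt",
) -> pd.DataFrame:
    """Full behavioral summary per condition: accuracies, median go RT,
    median SSD, and integration-method SSRT."""
    if ssd_central not in ("median", "mean"):
        raise ValueError("ssd_central must be 'median' or 'mean'")
    out = summarize_accuracy(trials)
    med_rt, med_ssd_, ssrt = [], [], []
    for cond in out["condition"]:
        grp = trials[trials["condition"] == cond]
        go = grp[grp["trial_type"] == "go"]
        stop = grp[grp["trial_type"] == "stop"]
        rts = go.loc[go["responded"], "rt_ms"].to_numpy()
        n_omit = int((~go["responded"]).sum())
        p_resp = float(stop["responded"].mean()) if len(stop) else np.nan
        ssds = stop["ssd_ms"].dropna()
        central = float(ssds.median() if ssd_central == "median" else ssds.mean()) if len(ssds) else np.nan
        med_rt.append(median_go_rt(grp))
        med_ssd_.append(median_ssd(grp))
        ssrt.append(
            estimate_ssrt_integration(rts, p_resp, central, n_omit, omission_correction)
            if np.isfinite(central)
            else float("nan")
        )
    out["median_go_rt_ms"] = med_rt
    out["median_ssd_ms"] = med_ssd_
    out["ssrt_ms"] = ssrt
    return out
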