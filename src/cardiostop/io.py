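"""On-disk formats: HDF5 session container, TSV tables, run manifest.

Signals (EEG, ECG, timeline arrays, montage) live in one HDF5 container
with a group per subject; tabular data (events, trials, summaries) are
TSVs. Writing then reading preserves signals bit-exactly and TSV fields
exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import SessionConfig
from .simulate import CardiacTimeline, EcgSignal, SimulatedSession, template_ground_truth

EVENT_COLUMNS = [
    "subject", "trial_id", "block", "condition", "event_type",
    "time_s", "cardiac_offset_ms", "outcome",
]
TRIAL_COLUMNS = [
    "subject", "trial_id", "block", "condition", "trial_type", "trial_start_s",
    "go_cue_time_s", "n_pre_cue_beats", "extended", "ssd_ms",
    "responded", "rt_ms", "outcome", "feedback_time_s", "trial_end_s",
]


def save_sessions(out_dir: str | Path, sessions: list[SimulatedSession]) -> dict[str, Path]:
    """Write sessions: ``sessions.h5`` (signals), ``events.tsv``,
    ``trials.tsv``, ``config.yaml``. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5_path = out / "sessions.h5"
    cfg = sessions[0].config
    with h5py.File(h5_path, "w") as f:
        f.attrs["n_subjects"] = len(sessions)
        f.attrs["config_yaml"] = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
        for i, s in enumerate(sessions):
            g = f.create_group(f"subject_{i:02d}")
            g.attrs["fs"] = s.fs
            g.create_dataset("ecg", data=s.ecg.samples)
            g.create_dataset("ecg_r_indices", data=s.ecg.true_r_indices)
            g.create_dataset("r_peak_times", data=s.timeline.r_peak_times)
            g.create_dataset("rr_intervals", data=s.timeline.rr_intervals)
            g.create_dataset("t_end_offsets", data=s.timeline.t_end_offsets)
            g.create_dataset(
                "channels", data=np.array(s.channels, dtype=h5py.string_dtype())
            )
            g.create_dataset(
                "montage_xyz_cm", data=s.montage[["x_cm", "y_cm", "z_cm"]].to_numpy()
            )
            if s.eeg is not None:
                g.create_dataset("eeg", data=s.eeg)
    events = pd.concat(
        [s.events.assign(subject=i) for i, s in enumerate(sessions)], ignore_index=True
    )[EVENT_COLUMNS]
    trials = pd.concat(
        [s.trials.assign(subject=i) for i, s in enumerate(sessions)], ignore_index=True
    )[TRIAL_COLUMNS]
    ev_path, tr_path, cfg_path = out / "events.tsv", out / "trials.tsv", out / "config.yaml"
    events.to_csv(ev_path, sep="\t", index=False, float_format="%.6f")
    trials.to_csv(tr_path, sep="\t", index=False, float_format="%.6f")
    cfg.to_yaml(cfg_path)
    return {"sessions": h5_path, "events": ev_path, "trials": tr_path, "config": cfg_path}


def load_sessions(out_dir: str | Path) -> list[SimulatedSession]:
    """Reload simulated sessions written by :func:`save_sessions`."""
    out = Path(out_dir)
    h5_path = out / "sessions.h5"
    if not h5_path.exists():
        raise FileNotFoundError(f"missing session container: {h5_path}")
    events = pd.read_csv(out / "events.tsv", sep="\t")
    trials = pd.read_csv(out / "trials.tsv", sep="\t")
    events["outcome"] = events["outcome"].fillna("")
    sessions: list[SimulatedSession] = []
    with h5py.File(h5_path, "r") as f:
        cfg = SessionConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        for i in range(int(f.attrs["n_subjects"])):
            g = f[f"subject_{i:02d}"]
            timeline = CardiacTimeline(
                g["r_peak_times"][:], g["rr_intervals"][:], g["t_end_offsets"][:]
            )
            labels = [c.decode() if isinstance(c, bytes) else str(c) for c in g["channels"][:]]
            montage = pd.DataFrame(
                g["montage_xyz_cm"][:], columns=["x_cm", "y_cm", "z_cm"]
            )
            montage.insert(0, "label", labels)
            ecg = EcgSignal(g["ecg"][:], float(g.attrs["fs"]), g["ecg_r_indices"][:])
            eeg = g["eeg"][:] if "eeg" in g else None
            ground_truth = template_ground_truth(cfg)
            sessions.append(
                SimulatedSession(
                    config=cfg,
                    timeline=timeline,
                    ecg=ecg,
                    eeg=eeg,
                    montage=montage,
                    events=events[events["subject"] == i].drop(columns="subject").reset_index(drop=True),
                    trials=trials[trials["subject"] == i].drop(columns="subject").reset_index(drop=True),
                    ground_truth=ground_truth,
                )
            )
    return sessions


def config_hash(config: SessionConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def update_manifest(
    out_dir: str | Path,
    stage: str,
    seed: int | None,
    config: SessionConfig | None,
    inputs: list[str],
    outputs: list[str],
    warnings_: list[str] | None = None,
) -> Path:
    """Append one stage record to the run manifest (created on first use)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": []}
    from . import __version__

    manifest["stages"].append(
        {
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
            "package_version": __version__,
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "warnings": warnings_ or [],
        }
    )
    path.write_text(json.dumps(manifest, indent=2))
    return path
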