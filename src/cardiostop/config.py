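"""Session configuration: every design constant in one validated structure.

Defaults reproduce the study design this package models: 3 blocks
(systole-coupled, diastole-coupled, no-distractor) of 150 trials each
(100 go / 50 stop), go-cue 2.9-4.5 s into the trial after at least three
heartbeats, a 200/±50/750 ms staircase on the stop-signal delay, distractor
movement onsets at R+290 ms (systole) or R+0 ms (diastole) with ~70 ms
trigger-latency jitter, and a heart with mean rate 58.2 bpm and
RMSSD 53.5 ms.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

CONDITIONS = ("systole", "diastole", "none")


@dataclass
class RaceModelParams:
    """Independent-race agent: ex-Gaussian go finishing times racing a
    (near-)constant stop process.

    A response occurs on a stop trial iff the go process finishes before
    SSD + SSRT. ``omission_rate`` is the probability that the go process
    fails outright (no response on a go trial; a "successful" stop for the
    wrong reason on stop trials).
    """

    go_mu: float = 400.0
    go_sigma: float = 40.0
    go_tau: float = 60.0
    ssrt_true: float = 220.0
    ssrt_sd: float = 0.0
    omission_rate: float = 0.08
    overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("go_mu", "go_sigma", "go_tau", "ssrt_true"):
            if getattr(self, name) <= 0 and name != "go_sigma":
                raise ValueError(f"{name} must be positive")
        if self.go_sigma < 0 or self.ssrt_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        if not 0.0 <= self.omission_rate <= 1.0:
            raise ValueError("omission_rate must lie in [0, 1]")

    def for_condition(self, condition: str) -> "RaceModelParams":
        """Parameters with any per-condition overrides applied."""
        ov = self.overrides.get(condition)
        if not ov:
            return self
        return dataclasses.replace(self, overrides={}, **ov)


# ERP template gains per condition. Directions follow the reported effects:
# P2 to distractor movement larger at diastole than systole; stop-locked N2
# smaller at diastole; commission-feedback P3 larger at systole; HEP smaller
# at diastole. Magnitudes are this package's own defaults (see docs).
DEFAULT_TEMPLATE_GAINS: dict[str, dict[str, float]] = {
    "hep": {"systole": 1.0, "diastole": 0.5, "none": 1.0},
    "p2": {"systole": 0.75, "diastole": 1.25, "none": 0.0},
    "go": {"systole": 1.0, "diastole": 1.0, "none": 1.0},
    "n2": {"systole": 1.0, "diastole": 0.5, "none": 1.0},
    "p3": {"systole": 1.5, "diastole": 1.0, "none": 1.0},
}


@dataclass
class SessionConfig:
    # Trial counts
    n_blocks: int = 3
    trials_per_block: int = 150
    go_per_block: int = 100
    stop_per_block: int = 50
    # Timing (seconds unless suffixed _ms)
    pre_cue_window: tuple[float, float] = (2.9, 4.5)
    min_heartbeats_pre_cue: int = 3
    max_heartbeats_pre_cue: int = 5
    go_display: float = 1.5
    stop_display: float = 1.0
    feedback_display: float = 1.0
    iti: float = 0.5
    # Cardiac coupling
    systole_offset_ms: float = 290.0
    diastole_offset_ms: float = 0.0
    trigger_jitter_sd_ms: float = 70.0
    # Staircase
    staircase_base_ms: float = 200.0
    staircase_step_ms: float = 50.0
    staircase_max_ms: float = 750.0
    staircase_floor_ms: float = 50.0
    # Physiology
    mean_hr_bpm: float = 58.2
    rmssd_ms: float = 53.5
    # Recording
    fs: float = 500.0
    montage_id: str = "standard64"
    channels: list[str] | None = None  # optional montage subset
    noise_sd_uv: float = 5.0
    ecg_noise_sd_uv: float = 5.0
    cfa_gain: float = 1.0
    render_eeg: bool = True
    # Agent and injected effects
    race: RaceModelParams = field(default_factory=RaceModelParams)
    template_gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEMPLATE_GAINS.items()}
    )
    # Design
    counterbalance_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.go_per_block + self.stop_per_block != self.trials_per_block:
            raise ValueError("go_per_block + stop_per_block must equal trials_per_block")
        for name in ("go_display", "stop_display", "feedback_display", "iti", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pre_cue_window
        if not (0 < lo <= hi):
            raise ValueError("pre_cue_window must be an increasing positive pair")
        if not (0 < self.staircase_floor_ms <= self.staircase_base_ms <= self.staircase_max_ms):
            raise ValueError("staircase constants must satisfy floor <= base <= max")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("counts must be positive")
        if isinstance(self.race, dict):
            self.race = RaceModelParams(**self.race)
        if isinstance(self.pre_cue_window, list):
            self.pre_cue_window = tuple(self.pre_cue_window)

    @property
    def block_order(self) -> tuple[str, ...]:
        """Condition order for this session's counterbalancing slot."""
        orders = list(itertools.permutations(CONDITIONS))
        return orders[self.counterbalance_index % len(orders)]

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def coupling_offset_ms(self, condition: str) -> float | None:
        if condition == "systole":
            return self.systole_offset_ms
        if condition == "diastole":
            return self.diastole_offset_ms
        return None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pre_cue_window"] = list(self.pre_cue_window)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SessionConfig":
        d = dict(d)
        if "pre_cue_window" in d:
            d["pre_cue_window"] = tuple(d["pre_cue_window"])
        if "race" in d and isinstance(d["race"], dict):
            d["race"] = RaceModelParams(**d["race"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def trial_length_bounds(config: SessionConfig) -> tuple[float, float]:
    """Analytic (min, max) trial span in seconds, excluding the ITI.

    The span runs from trial start to the end of the feedback screen:
    cue delay + response window + feedback display. With the default
    2.9-4.5 s cue window this is 5.4-7.0 s.
    """
    lo, hi = config.pre_cue_window
    tail = config.go_display + config.feedback_display
    return (lo + tail, hi + tail)
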