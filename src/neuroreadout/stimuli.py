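"""Stimulus and trial-table containers.

A trial table is a pandas DataFrame with one row per 2AFC trial and the
column contract given by :data:`TRIAL_COLUMNS`.  Contrast and coherence are
proportions in [0, 1] everywhere inside the package; percent appears only at
I/O boundaries chosen by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Stimulus",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_events",
    "write_events",
]

#: Column contract for trials.csv.
TRIAL_COLUMNS = [
    "trial_id",
    "run_id",
    "task",
    "base_con",
    "base_coh",
    "delta_con",
    "delta_coh",
    "target_side_con",
    "target_side_coh",
    "stim_con_left",
    "stim_con_right",
    "stim_coh_left",
    "stim_coh_right",
    "is_catch",
    "post_cue",
    "choice",
    "correct",
]

#: Extra columns filled in once an observer's choices are simulated.
HISTORY_COLUMNS = ["prev_choice", "prev_correct"]


@dataclass(frozen=True)
class Stimulus:
    """One dot patch: absolute contrast and motion coherence.

    Contrast is Michelson-style with a 0.25 baseline always on screen;
    coherence is the fraction of coherently moving dots (baseline 0).
    """

    contrast: float
    coherence: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0 and 0.0 <= self.coherence <= 1.0):
            raise ValueError(
                f"stimulus out of the unit box: contrast={self.contrast}, coherence={self.coherence}"
            )


@dataclass
class TrialRecord:
    """One 2AFC trial; mirrors one row of the trial table."""

    trial_id: int
    run_id: int
    task: str  # "contrast" | "coherence"
    left: Stimulus
    right: Stimulus
    target_side_con: str
    target_side_coh: str
    delta_con: float
    delta_coh: float
    is_catch: bool = False
    post_cue: str = "none"
    choice: str = "none"
    correct: bool | None = None
    prev_choice: str = "none"
    prev_correct: bool | None = None

    @property
    def judged_feature(self) -> str:
        """Feature the observer must report: the post-cue on catch trials."""
        return self.post_cue if self.is_catch else self.task

    @classmethod
    def from_row(cls, row: pd.Series) -> "TrialRecord":
        return cls(
            trial_id=int(row["trial_id"]),
            run_id=int(row["run_id"]),
            task=str(row["task"]),
            left=Stimulus(float(row["stim_con_left"]), float(row["stim_coh_left"])),
            right=Stimulus(float(row["stim_con_right"]), float(row["stim_coh_right"])),
            target_side_con=str(row["target_side_con"]),
            target_side_coh=str(row["target_side_coh"]),
            delta_con=float(row["delta_con"]),
            delta_coh=float(row["delta_coh"]),
            is_catch=bool(row["is_catch"]),
            post_cue=str(row["post_cue"]),
            choice=str(row.get("choice", "none")),
            correct=None if pd.isna(row.get("correct")) else bool(row.get("correct")),
            prev_choice=str(row.get("prev_choice", "none")),
            prev_correct=None if pd.isna(row.get("prev_correct")) else bool(row.get("prev_correct")),
        )


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    cols = TRIAL_COLUMNS + [c for c in HISTORY_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("onset_volume", "condition_id", "condition_label"):
        if c not in df.columns:
            raise ValueError(f"event schedule missing column {c!r}")
    return df


def write_events(df: pd.DataFrame, path) -> None:
    df.loc[:, ["onset_volume", "condition_id", "condition_label"]].to_csv(path, index=False)
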