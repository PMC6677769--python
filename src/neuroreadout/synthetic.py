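"""Synthetic task schedules, observers, staircases and BOLD timeseries.

This module emulates the two-feature motion-visibility experiment: blocks
(runs) of 2AFC trials cued to report either contrast or coherence, both
features incremented on every trial with independent target sides, the cued
increment controlled by a PEST staircase, rare post-cued catch trials in a
subset of runs, and event-related BOLD responses built by linear summation
of HRF-shaped condition responses with additive Gaussian noise.

Defaults reproduce the study conditions: base increments +7.5/+15/+30/+60%
contrast (above the 25% baseline) and +15/+30/+45/+60% coherence, catch
trials at probability 1/7 in 2/5 of runs, exponential inter-trial intervals
with mean 6 s truncated to 2–11 s, TR 0.5 s, 32 scan conditions (4 x 4 base
grid x 2 tasks).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._util import as_rng, rng_for
from .linking import ReadoutModel, choice_probabilities, prf_sets_by_task
from .staircase import PestStaircase, StaircaseState, WeibullObserver, run_pest_staircase  # noqa: F401

__all__ = [
    "TaskConfig",
    "BoldTimeseries",
    "ConfigError",
    "generate_task_schedule",
    "simulate_observer",
    "simulate_behavioral_session",
    "simulate_bold_timeseries",
    "double_gamma_hrf",
    "condition_amplitudes",
    "condition_label",
    "run_pest_staircase",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent task configuration."""


@dataclass
class TaskConfig:
    """Parameters of the behavioral task and scan schedule."""

    base_con_increments: tuple[float, ...] = (0.075, 0.15, 0.30, 0.60)
    base_coh_increments: tuple[float, ...] = (0.15, 0.30, 0.45, 0.60)
    delta_con_menu: tuple[float, ...] = (0.0, 0.018, 0.025, 0.035, 0.049, 0.069, 0.095, 0.133, 0.185)
    delta_coh_menu: tuple[float, ...] = (0.0, 0.05, 0.069, 0.096, 0.134, 0.186, 0.259, 0.361, 0.502)
    baseline_contrast: float = 0.25
    catch_run_fraction: float = 0.4
    catch_trial_prob: float = 1.0 / 7.0
    iti_mean_s: float = 6.0
    iti_range_s: tuple[float, float] = (2.0, 11.0)
    trials_per_run: int = 50
    n_runs: int = 10
    staircase_target: float = 0.82
    staircase_init_contrast: float = 0.25
    staircase_init_coherence: float = 0.85
    staircase_init_step: float | None = None
    tr_s: float = 0.5
    trial_duration_s: float = 2.0
    run_baseline_s: float = 30.0
    tail_s: float = 40.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("catch_run_fraction", "catch_trial_prob", "staircase_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} is not a probability")
        lo, hi = self.iti_range_s
        if lo >= hi:
            raise ConfigError(f"ITI range inverted: {self.iti_range_s}")
        if not lo <= self.iti_mean_s <= hi:
            raise ConfigError("ITI mean outside its range")
        if self.trials_per_run < 1 or self.n_runs < 1:
            raise ConfigError("need at least one trial and one run")
        for inc in self.base_con_increments:
            if not 0.0 <= self.baseline_contrast + inc <= 1.0:
                raise ConfigError(f"contrast base {inc} exceeds the display range")
        for inc in self.base_coh_increments:
            if not 0.0 <= inc <= 1.0:
                raise ConfigError(f"coherence base {inc} exceeds the display range")

    @property
    def n_conditions(self) -> int:
        return len(self.base_con_increments) * len(self.base_coh_increments) * 2

    def base_contrasts(self) -> np.ndarray:
        """Absolute base contrasts (baseline + increment)."""
        return self.baseline_contrast + np.asarray(self.base_con_increments)

    def base_coherences(self) -> np.ndarray:
        return np.asarray(self.base_coh_increments)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        d = dict(d)
        for k in ("base_con_increments", "base_coh_increments", "delta_con_menu", "delta_coh_menu", "iti_range_s"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class BoldTimeseries:
    """Percent-signal-change samples from one area/hemisphere at fixed TR."""

    area: str
    hemisphere: str
    tr_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD timeseries contains non-finite values")


# ---------------------------------------------------------------------------
# inter-trial intervals


def _truncated_exp_scale(mean: float, lo: float, hi: float) -> float:
    """Scale of an exponential whose truncation to [lo, hi] has the given mean."""
    width = hi - lo

    def trunc_mean(theta: float) -> float:
        # E[T | lo <= T <= hi] for T ~ Exp(theta), shifted formulation
        ratio = width / theta
        if ratio > 700.0:  # exp overflow guard; correction term is ~0 there
            return lo + theta
        return lo + theta - width / np.expm1(ratio)

    return brentq(lambda th: trunc_mean(th) - mean, 1e-3, 1e3)


def sample_itis(n: int, cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Exponential ITIs truncated to the configured range (inverse-CDF draw)."""
    lo, hi = cfg.iti_range_s
    theta = _truncated_exp_scale(cfg.iti_mean_s, lo, hi)
    u = rng.random(n)
    a, b = np.exp(-lo / theta), np.exp(-hi / theta)
    return -theta * np.log(a - u * (a - b))


# ---------------------------------------------------------------------------
# schedules


def condition_label(con_idx: int, coh_idx: int, task: str) -> str:
    return f"con{con_idx}_coh{coh_idx}_task{task}"


def generate_task_schedule(
    cfg: TaskConfig,
    seed: int | None = None,
    *,
    scan_mode: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate a full session of trials (choices unset) and, in scan mode,
    the event schedule of onset volumes.

    Runs alternate task cues; catch runs (the configured fraction, split
    across tasks) restrict bases to the lowest level and contain rare
    post-cued catch trials.  Base levels and target sides are independent
    uniform draws per trial, so each condition is equally likely to follow
    any other.  Cued-feature deltas here are placeholder draws from the
    printed menus; staircase-coupled simulation replaces them
    (:func:`simulate_behavioral_session`).  Scan mode emits no catch trials.
    """
    rng = as_rng(cfg.seed if seed is None else seed)
    n_con = len(cfg.base_con_increments)
    n_coh = len(cfg.base_coh_increments)
    bases_con = cfg.base_contrasts()
    bases_coh = cfg.base_coherences()

    n_catch_runs = 0 if scan_mode else int(round(cfg.catch_run_fraction * cfg.n_runs))
    run_order = rng.permutation(cfg.n_runs)
    catch_runs = set(run_order[:n_catch_runs].tolist())

    rows = []
    trial_id = 0
    for run_id in range(cfg.n_runs):
        task = "contrast" if run_id % 2 == 0 else "coherence"
        other = "coherence" if task == "contrast" else "contrast"
        is_catch_run = run_id in catch_runs
        for _ in range(cfg.trials_per_run):
            # catch runs use a single (lowest) base level per feature
            ci = 0 if is_catch_run else rng.integers(n_con)
            hi = 0 if is_catch_run else rng.integers(n_coh)
            side_con = "right" if rng.random() < 0.5 else "left"
            side_coh = "right" if rng.random() < 0.5 else "left"
            d_con = float(rng.choice(cfg.delta_con_menu))
            d_coh = float(rng.choice(cfg.delta_coh_menu))
            is_catch = bool(is_catch_run and rng.random() < cfg.catch_trial_prob)
            base_c, base_h = float(bases_con[ci]), float(bases_coh[hi])
            rows.append(
                {
                    "trial_id": trial_id,
                    "run_id": run_id,
                    "task": task,
                    "base_con": base_c,
                    "base_coh": base_h,
                    "delta_con": d_con,
                    "delta_coh": d_coh,
                    "target_side_con": side_con,
                    "target_side_coh": side_coh,
                    "stim_con_left": min(1.0, base_c + (d_con if side_con == "left" else 0.0)),
                    "stim_con_right": min(1.0, base_c + (d_con if side_con == "right" else 0.0)),
                    "stim_coh_left": min(1.0, base_h + (d_coh if side_coh == "left" else 0.0)),
                    "stim_coh_right": min(1.0, base_h + (d_coh if side_coh == "right" else 0.0)),
                    "is_catch": is_catch,
                    "post_cue": other if is_catch else "none",
                    "choice": "none",
                    "correct": np.nan,
                    "con_idx": ci,
                    "coh_idx": hi,
                }
            )
            trial_id += 1
    trials = pd.DataFrame(rows)

    events = None
    if scan_mode:
        itis = sample_itis(len(trials), cfg, rng)
        onsets = []
        t = 0.0
        i = 0
        for run_id in range(cfg.n_runs):
            t += cfg.run_baseline_s
            for _ in range(cfg.trials_per_run):
                onsets.append(t)
                t += cfg.trial_duration_s + itis[i]
                i += 1
        onset_vol = np.round(np.asarray(onsets) / cfg.tr_s).astype(int)
        cond_id = (
            (trials["task"] == "coherence").to_numpy(dtype=int) * (n_con * n_coh)
            + trials["con_idx"].to_numpy() * n_coh
            + trials["coh_idx"].to_numpy()
        )
        labels = [
            condition_label(ci, hi, tk)
            for ci, hi, tk in zip(trials["con_idx"], trials["coh_idx"], trials["task"])
        ]
        events = pd.DataFrame(
            {"onset_volume": onset_vol, "condition_id": cond_id, "condition_label": labels}
        )
        events.attrs["n_volumes"] = int(np.ceil((t + cfg.tail_s) / cfg.tr_s))
    return trials, events


# ---------------------------------------------------------------------------
# observers


def simulate_observer(
    trials: pd.DataFrame,
    truth: ReadoutModel,
    prf_sets,
    seed,
) -> pd.DataFrame:
    """Draw trial-by-trial choices from a ground-truth linking model.

    Choices are Bernoulli draws at the model's P(right); correctness is
    judged against the target side of the feature the observer must report
    (the post-cue on catch trials).  prev_choice/prev_correct are filled per
    run (first trial of a run has no history).  When the truth carries
    history terms, trials are simulated sequentially within runs.
    """
    if (trials["stim_con_left"].isna() | trials["stim_con_right"].isna()).any():
        raise ValueError("schedule has unset stimuli")
    rng = as_rng(seed)
    df = trials.copy()
    feature = np.where(df["is_catch"].to_numpy(dtype=bool), df["post_cue"], df["task"]).astype(str)
    target = np.where(
        feature == "contrast", df["target_side_con"].astype(str), df["target_side_coh"].astype(str)
    )

    if truth.history is None:
        p_right = choice_probabilities(truth, prf_sets, df)
        choice = np.where(rng.random(len(df)) < p_right, "right", "left")
    else:
        choice = np.empty(len(df), dtype=object)
        df["prev_choice"] = "none"
        df["prev_correct"] = np.nan
        run_ids = df["run_id"].to_numpy()
        u = rng.random(len(df))
        for run in np.unique(run_ids):
            idx = np.flatnonzero(run_ids == run)
            prev_choice, prev_ok = "none", np.nan
            for i in idx:
                df.iat[i, df.columns.get_loc("prev_choice")] = prev_choice
                df.iat[i, df.columns.get_loc("prev_correct")] = prev_ok
                p = choice_probabilities(truth, prf_sets, df.iloc[[i]])[0]
                c = "right" if u[i] < p else "left"
                choice[i] = c
                prev_choice, prev_ok = c, bool(c == target[i])
        choice = choice.astype(str)

    df["choice"] = choice
    df["correct"] = choice == target
    # history bookkeeping within runs
    grp = df.groupby("run_id", sort=False)
    df["prev_choice"] = grp["choice"].shift(1).fillna("none")
    df["prev_correct"] = grp["correct"].shift(1)
    return df


def simulate_behavioral_session(
    cfg: TaskConfig,
    truth: ReadoutModel,
    prf_sets,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full behavioral session: schedule + per-condition PEST staircases
    driving the cued deltas + generative choices.

    One independent staircase per (task, base level of the cued feature),
    mirroring the 4 x 2 = 8 staircases of the non-catch session structure.
    """
    seed = cfg.seed if seed is None else seed
    trials, _ = generate_task_schedule(cfg, seed=rng_for(seed, "schedule").integers(2**31))
    rng = rng_for(seed, "choices")

    stairs: dict[tuple[str, int], PestStaircase] = {}
    for task in ("contrast", "coherence"):
        n_bases = len(cfg.base_con_increments if task == "contrast" else cfg.base_coh_increments)
        init = cfg.staircase_init_contrast if task == "contrast" else cfg.staircase_init_coherence
        for bi in range(n_bases):
            base = (cfg.base_contrasts() if task == "contrast" else cfg.base_coherences())[bi]
            stairs[(task, bi)] = PestStaircase(
                initial_level=min(init, 1.0 - base),
                initial_step=cfg.staircase_init_step,
                target=cfg.staircase_target,
                bounds=(1e-4, max(1e-3, 1.0 - base)),
            )

    df = trials.copy()
    feature = np.where(df["is_catch"].to_numpy(dtype=bool), df["post_cue"], df["task"]).astype(str)
    cols = {c: df.columns.get_loc(c) for c in df.columns}
    choices = np.empty(len(df), dtype=object)
    corrects = np.empty(len(df), dtype=bool)
    u = rng.random(len(df))
    for i in range(len(df)):
        task = df.iat[i, cols["task"]]
        bi = int(df.iat[i, cols["con_idx"]] if task == "contrast" else df.iat[i, cols["coh_idx"]])
        stair = stairs[(task, bi)]
        level = stair.level
        # write the staircased cued delta into the trial stimuli
        if task == "contrast":
            df.iat[i, cols["delta_con"]] = level
            side = df.iat[i, cols["target_side_con"]]
            base = df.iat[i, cols["base_con"]]
            df.iat[i, cols["stim_con_left"]] = min(1.0, base + (level if side == "left" else 0.0))
            df.iat[i, cols["stim_con_right"]] = min(1.0, base + (level if side == "right" else 0.0))
        else:
            df.iat[i, cols["delta_coh"]] = level
            side = df.iat[i, cols["target_side_coh"]]
            base = df.iat[i, cols["base_coh"]]
            df.iat[i, cols["stim_coh_left"]] = min(1.0, base + (level if side == "left" else 0.0))
            df.iat[i, cols["stim_coh_right"]] = min(1.0, base + (level if side == "right" else 0.0))
        p_right = choice_probabilities(truth, prf_sets, df.iloc[[i]])[0]
        c = "right" if u[i] < p_right else "left"
        feat = feature[i]
        tgt = df.iat[i, cols["target_side_con"] if feat == "contrast" else cols["target_side_coh"]]
        ok = c == tgt
        choices[i] = c
        corrects[i] = ok
        # catch trials do not feed the cued staircase (no feedback given)
        if not df.iat[i, cols["is_catch"]]:
            stair.update(ok)
    df["choice"] = choices.astype(str)
    df["correct"] = corrects
    grp = df.groupby("run_id", sort=False)
    df["prev_choice"] = grp["choice"].shift(1).fillna("none")
    df["prev_correct"] = grp["correct"].shift(1)
    return df


# ---------------------------------------------------------------------------
# BOLD


def double_gamma_hrf(
    tr_s: float = 0.5,
    duration_s: float = 40.5,
    peak_s: float = 5.5,
    undershoot_s: float = 15.0,
    peak_disp: float = 1.0,
    under_disp: float = 3.0,
    under_ratio: float = 0.3,
) -> np.ndarray:
    """Canonical difference-of-gammas HRF sampled at TR, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, duration_s, tr_s)
    peak = gamma_dist.pdf(t, peak_s / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_s / under_disp, scale=under_disp)
    h = peak - under_ratio * under
    return h / np.max(h)


def simulate_bold_timeseries(
    events: pd.DataFrame,
    amplitudes: Sequence[float] | Mapping[int, float],
    hrf_kernel: np.ndarray,
    noise_sd: float,
    seed,
    *,
    n_volumes: int | None = None,
    area: str = "V1",
    hemisphere: str = "left",
    tr_s: float = 0.5,
    ar1: float = 0.0,
) -> BoldTimeseries:
    """Linear-summation BOLD: amplitude-scaled kernels at event onsets plus
    i.i.d. Gaussian noise (optionally AR(1), off by default)."""
    kernel = np.asarray(hrf_kernel, dtype=float)
    if n_volumes is None:
        n_volumes = int(events.attrs.get("n_volumes", 0)) or int(events["onset_volume"].max() + len(kernel))
    if len(kernel) > n_volumes:
        raise ValueError("HRF kernel longer than the timeseries")
    if isinstance(amplitudes, Mapping):
        amp = dict(amplitudes)
    else:
        amp = {i: a for i, a in enumerate(amplitudes)}
    missing = sorted(set(events["condition_id"]) - set(amp))
    if missing:
        raise ValueError(f"no amplitude given for condition(s) {missing}")

    y = np.zeros(n_volumes)
    for onset, cond in zip(events["onset_volume"].to_numpy(), events["condition_id"].to_numpy()):
        if onset < 0 or onset >= n_volumes:
            raise ValueError(f"event onset {onset} outside [0, {n_volumes})")
        stop = min(onset + len(kernel), n_volumes)
        y[onset:stop] += amp[int(cond)] * kernel[: stop - onset]
    if noise_sd > 0:
        rng = as_rng(seed)
        eps = rng.normal(0.0, noise_sd, n_volumes)
        if ar1:
            for i in range(1, n_volumes):
                eps[i] += ar1 * eps[i - 1]
        y = y + eps
    return BoldTimeseries(area=area, hemisphere=hemisphere, tr_s=tr_s, values=y)


def condition_amplitudes(
    prf_by_task: Mapping[str, Mapping[str, "object"]] | Mapping[str, "object"],
    cfg: TaskConfig,
    area: str,
) -> np.ndarray:
    """Ground-truth scalar amplitude per scan condition for one area.

    Condition ids are ordered task-major (contrast task first), then base
    contrast, then base coherence — matching :func:`generate_task_schedule`.
    """
    by_task = prf_sets_by_task(prf_by_task)
    out = []
    for task in ("contrast", "coherence"):
        prf = by_task[task][area]
        for bc in cfg.base_contrasts():
            for bh in cfg.base_coherences():
                out.append(float(prf.response(bc, bh)))
    return np.asarray(out)
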