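"""Probit linking model: from population responses to 2AFC choices.

The decision variable on each trial is the difference between the weighted
cortical responses evoked by the right and left dot patches, plus a side
bias, passed through a standard-normal CDF (probit link):

    P(right) = lapse/2 + (1 - lapse) * Phi(Sum_right - Sum_left + beta_bias)

where Sum_side = sum_area beta_area * R_area(s_con, s_coh).  A *fixed*
readout shares one weight per area across the two tasks; a *flexible*
readout fits an independent weight set per task.

Variants:

* history — four stay/switch predictors (previous choice side x previous
  correctness) added inside the probit argument.
* efficient selection — area responses are raised to an exponent rho before
  weighting and the rho-th root of the aggregate is taken (signed powers so
  negative responses stay defined).
* Poisson noise — the probit scale is set per trial from the unweighted mean
  population response of the two patches (variance grows with response),
  instead of the unit variance of the additive model.

Because the additive model fixes the probit noise at sigma = 1, fitted
weights are interpretable: 1/beta_area is the implied noise of that area's
representation in percent signal change, and the analytic JND at a base
stimulus is the increment that raises the weighted readout by exactly one
(d' = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtr

from ._util import as_rng
from .response import PopulationResponseFunction
from .stimuli import Stimulus, TrialRecord

__all__ = [
    "ReadoutModel",
    "FitResult",
    "TASKS",
    "choice_probability",
    "choice_probabilities",
    "fit_readout",
    "implied_noise",
    "predict_jnd",
    "predict_catch_jnd",
    "simulated_jnd",
    "PCORRECT_DPRIME1",
]

TASKS = ("contrast", "coherence")
HISTORY_KEYS = ("left_correct", "right_correct", "left_incorrect", "right_incorrect")

#: 2AFC percent correct at d' = 1: Phi(1/sqrt(2)) ~ 0.760.
PCORRECT_DPRIME1 = float(ndtr(1.0 / np.sqrt(2.0)))

_PCLIP = 1e-12
_SIGMA2_FLOOR = 1e-12


def _other(task: str) -> str:
    return "coherence" if task == "contrast" else "contrast"


@dataclass
class ReadoutModel:
    """Weighted readout of cortical population responses plus decision stage."""

    areas: tuple[str, ...]
    weights: dict[str, dict[str, float]]  # task -> area -> weight
    beta_bias: float = 0.0
    lapse: float = 0.0
    readout_mode: str = "flexible"  # "fixed" | "flexible"
    noise_mode: str = "additive"  # "additive" | "poisson"
    selection_rho: float | None = None
    history: dict[str, float] | None = None
    poisson_combine: str = "mean"  # "mean" | "sum" of the two patch variances

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be a probability, got {self.lapse}")
        if self.readout_mode not in ("fixed", "flexible"):
            raise ValueError(f"unknown readout_mode {self.readout_mode!r}")
        if self.noise_mode not in ("additive", "poisson"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.selection_rho is not None and self.selection_rho < 1.0:
            raise ValueError("selection_rho must be >= 1")
        for task in TASKS:
            if task not in self.weights:
                raise ValueError(f"weights missing task {task!r}")
            missing = [a for a in self.areas if a not in self.weights[task]]
            if missing:
                raise ValueError(f"weights[{task!r}] missing areas {missing}")
        if self.readout_mode == "fixed":
            wc, wh = self.weights["contrast"], self.weights["coherence"]
            if any(wc[a] != wh[a] for a in self.areas):
                raise ValueError("fixed readout requires identical weights across tasks")
        if self.history is not None:
            missing = [k for k in HISTORY_KEYS if k not in self.history]
            if missing:
                raise ValueError(f"history missing coefficients {missing}")

    @property
    def n_free_parameters(self) -> int:
        """Free parameters of the decision stage (weights + bias + variants)."""
        n_areas = len(self.areas)
        n = (n_areas if self.readout_mode == "fixed" else 2 * n_areas) + 1
        if self.history is not None:
            n += 4
        if self.selection_rho is not None:
            n += 1
        return n

    def weight_vector(self, task: str) -> np.ndarray:
        return np.array([self.weights[task][a] for a in self.areas])

    def to_dict(self) -> dict:
        return {
            "areas": list(self.areas),
            "weights": {t: dict(self.weights[t]) for t in TASKS},
            "beta_bias": self.beta_bias,
            "lapse": self.lapse,
            "readout_mode": self.readout_mode,
            "noise_mode": self.noise_mode,
            "selection_rho": self.selection_rho,
            "history": dict(self.history) if self.history else None,
            "poisson_combine": self.poisson_combine,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReadoutModel":
        d = dict(d)
        d["areas"] = tuple(d["areas"])
        return cls(**d)


@dataclass
class FitResult:
    model: ReadoutModel
    loglik: float
    n_restarts: int
    converged: bool
    implied_noise: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# probability machinery


def prf_sets_by_task(prf_sets) -> dict[str, dict[str, PopulationResponseFunction]]:
    """Normalize a PRF argument to {task: {area: PRF}}.

    Accepts either one shared {area: PRF} mapping or a per-task mapping.
    """
    if set(prf_sets) == set(TASKS):
        return {t: dict(prf_sets[t]) for t in TASKS}
    return {t: dict(prf_sets) for t in TASKS}


def _response_matrix(prf_set, areas, con, coh) -> np.ndarray:
    """(n, n_areas) matrix of area responses to patches (con, coh)."""
    return np.column_stack([prf_set[a].response(con, coh) for a in areas])


def _signed_pow(x, p):
    return np.sign(x) * np.abs(x) ** p


def _block_probability(
    model: ReadoutModel,
    r_left: np.ndarray,
    r_right: np.ndarray,
    w: np.ndarray,
    hist_design: np.ndarray | None,
) -> np.ndarray:
    """P(choose right) for one homogeneous block of trials.

    ``r_left``/``r_right`` are (n, n_areas) raw area responses; ``w`` is the
    weight vector that applies to every trial of the block.
    """
    if model.selection_rho is not None:
        rho = model.selection_rho
        s_l = _signed_pow(r_left, rho) @ w
        s_r = _signed_pow(r_right, rho) @ w
    else:
        s_l = r_left @ w
        s_r = r_right @ w

    z = s_r - s_l + model.beta_bias
    if hist_design is not None and model.history is not None:
        h = np.array([model.history[k] for k in HISTORY_KEYS])
        z = z + hist_design @ h

    if model.selection_rho is not None:
        z = _signed_pow(z, 1.0 / model.selection_rho)

    if model.noise_mode == "poisson":
        var_l = r_left.mean(axis=1)
        var_r = r_right.mean(axis=1)
        if model.poisson_combine == "sum":
            sigma2 = var_l + var_r
        else:
            sigma2 = 0.5 * (var_l + var_r)
        sigma2 = np.maximum(sigma2, _SIGMA2_FLOOR)
        z = z / np.sqrt(sigma2)

    lam = model.lapse
    return lam / 2.0 + (1.0 - lam) * ndtr(z)


def _history_design(df: pd.DataFrame) -> np.ndarray | None:
    if "prev_choice" not in df.columns:
        return None
    prev = df["prev_choice"].astype(str).to_numpy()
    prev_ok = df["prev_correct"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    cols = [
        (prev == "left") & prev_ok,
        (prev == "right") & prev_ok,
        (prev == "left") & ~prev_ok & (prev != "none"),
        (prev == "right") & ~prev_ok & (prev != "none"),
    ]
    return np.column_stack(cols).astype(float)


def choice_probabilities(model: ReadoutModel, prf_sets, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial P(choose right) for a trial table.

    The PRF set is selected by the run's task cue (the cortical state); the
    weight set is selected by the feature the observer must judge, which is
    the post-cued feature on catch trials.
    """
    by_task = prf_sets_by_task(prf_sets)
    tasks = trials["task"].astype(str).to_numpy()
    is_catch = trials["is_catch"].to_numpy(dtype=bool)
    feature = np.where(is_catch, trials["post_cue"].astype(str).to_numpy(), tasks)
    con_l = trials["stim_con_left"].to_numpy(dtype=float)
    con_r = trials["stim_con_right"].to_numpy(dtype=float)
    coh_l = trials["stim_coh_left"].to_numpy(dtype=float)
    coh_r = trials["stim_coh_right"].to_numpy(dtype=float)
    hist = _history_design(trials) if model.history is not None else None

    p = np.empty(len(trials))
    for task in TASKS:
        for feat in TASKS:
            m = (tasks == task) & (feature == feat)
            if not m.any():
                continue
            r_l = _response_matrix(by_task[task], model.areas, con_l[m], coh_l[m])
            r_r = _response_matrix(by_task[task], model.areas, con_r[m], coh_r[m])
            p[m] = _block_probability(
                model, r_l, r_r, model.weight_vector(feat), None if hist is None else hist[m]
            )
    return p


def choice_probability(model: ReadoutModel, prf_sets, trial: TrialRecord) -> float:
    """P(choose right) for a single trial record."""
    by_task = prf_sets_by_task(prf_sets)
    feat = trial.judged_feature
    r_l = _response_matrix(
        by_task[trial.task], model.areas, np.array([trial.left.contrast]), np.array([trial.left.coherence])
    )
    r_r = _response_matrix(
        by_task[trial.task], model.areas, np.array([trial.right.contrast]), np.array([trial.right.coherence])
    )
    hist = None
    if model.history is not None:
        prev_ok = bool(trial.prev_correct) if trial.prev_correct is not None else False
        hist = np.array(
            [[
                float(trial.prev_choice == "left" and prev_ok),
                float(trial.prev_choice == "right" and prev_ok),
                float(trial.prev_choice == "left" and not prev_ok),
                float(trial.prev_choice == "right" and not prev_ok),
            ]]
        )
    return float(_block_probability(model, r_l, r_r, model.weight_vector(feat), hist)[0])


def bernoulli_loglik(p_right: np.ndarray, chose_right: np.ndarray) -> float:
    """Total Bernoulli log-likelihood (nats) of observed choices."""
    p = np.clip(np.asarray(p_right, dtype=float), _PCLIP, 1.0 - _PCLIP)
    y = np.asarray(chose_right, dtype=bool)
    return float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


# ---------------------------------------------------------------------------
# fitting


def _pack_template(areas, readout_mode, history, selection):
    """Parameter layout: weights [+task2 weights], bias, [4 history], [rho]."""
    n_a = len(areas)
    n_w = n_a if readout_mode == "fixed" else 2 * n_a
    n = n_w + 1 + (4 if history else 0) + (1 if selection else 0)
    return n_a, n_w, n


def _unpack(x, areas, readout_mode, noise_mode, history, selection, lapse, poisson_combine):
    n_a, n_w, _ = _pack_template(areas, readout_mode, history, selection)
    if readout_mode == "fixed":
        w = dict(zip(areas, x[:n_a]))
        weights = {"contrast": dict(w), "coherence": dict(w)}
    else:
        weights = {
            "contrast": dict(zip(areas, x[:n_a])),
            "coherence": dict(zip(areas, x[n_a:n_w])),
        }
    i = n_w
    bias = float(x[i]); i += 1
    hist = None
    if history:
        hist = dict(zip(HISTORY_KEYS, [float(v) for v in x[i:i + 4]])); i += 4
    rho = float(x[i]) if selection else None
    return ReadoutModel(
        areas=tuple(areas),
        weights=weights,
        beta_bias=bias,
        lapse=lapse,
        readout_mode=readout_mode,
        noise_mode=noise_mode,
        selection_rho=rho,
        history=hist,
        poisson_combine=poisson_combine,
    )


def fit_readout(
    trials: pd.DataFrame,
    prf_sets,
    *,
    readout_mode: str = "flexible",
    noise_mode: str = "additive",
    areas: Sequence[str] | None = None,
    history: bool = False,
    selection: bool = False,
    lapse: float = 0.0,
    n_restarts: int = 6,
    seed: int = 0,
    weight_bound: float = 50.0,
    bias_bound: float = 10.0,
    rho_bound: float = 8.0,
    tol: float = 1e-8,
    poisson_combine: str = "mean",
) -> FitResult:
    """Maximum-likelihood fit of the readout weights (lapse held fixed).

    Multi-start bounded quasi-Newton optimisation of the Bernoulli
    log-likelihood; the first start is at zero weights, the remaining starts
    are seeded random draws.  Returns the best restart.
    """
    by_task = prf_sets_by_task(prf_sets)
    if areas is None:
        areas = list(next(iter(by_task.values())).keys())
    areas = list(areas)

    choices = trials["choice"].astype(str).to_numpy()
    if not np.isin(choices, ("left", "right")).all():
        raise ValueError("all trials must have a left/right choice before fitting")
    y = choices == "right"
    if y.all() or (~y).all():
        warnings.warn("degenerate trials: every choice on the same side; fit at boundary")

    tasks = trials["task"].astype(str).to_numpy()
    is_catch = trials["is_catch"].to_numpy(dtype=bool)
    feature = np.where(is_catch, trials["post_cue"].astype(str).to_numpy(), tasks)
    if readout_mode == "flexible":
        for t in TASKS:
            if not (feature == t).any():
                raise ValueError(f"flexible readout needs trials judging {t!r}")
    con_l = trials["stim_con_left"].to_numpy(dtype=float)
    con_r = trials["stim_con_right"].to_numpy(dtype=float)
    coh_l = trials["stim_coh_left"].to_numpy(dtype=float)
    coh_r = trials["stim_coh_right"].to_numpy(dtype=float)
    hist_all = _history_design(trials) if history else None
    if history and hist_all is None:
        raise ValueError("history variant requires prev_choice/prev_correct columns")

    # Precompute response matrices per (task, judged-feature) block.
    blocks = []
    for task in TASKS:
        for feat in TASKS:
            m = (tasks == task) & (feature == feat)
            if not m.any():
                continue
            blocks.append(
                (
                    feat,
                    _response_matrix(by_task[task], areas, con_l[m], coh_l[m]),
                    _response_matrix(by_task[task], areas, con_r[m], coh_r[m]),
                    y[m],
                    None if hist_all is None else hist_all[m],
                )
            )

    n_a, n_w, n_par = _pack_template(areas, readout_mode, history, selection)

    def nll(x: np.ndarray) -> float:
        model = _unpack(x, areas, readout_mode, noise_mode, history, selection, lapse, poisson_combine)
        total = 0.0
        for feat, r_l, r_r, y_b, h_b in blocks:
            p = _block_probability(model, r_l, r_r, model.weight_vector(feat), h_b)
            total += bernoulli_loglik(p, y_b)
        return -total

    bounds = [(-weight_bound, weight_bound)] * n_w + [(-bias_bound, bias_bound)]
    if history:
        bounds += [(-bias_bound, bias_bound)] * 4
    if selection:
        bounds += [(1.0, rho_bound)]

    rng = as_rng(seed)
    starts = [np.zeros(n_par)]
    if selection:
        starts[0][-1] = 1.5
    for _ in range(max(0, n_restarts - 1)):
        x0 = np.concatenate(
            [
                rng.uniform(-5.0, 5.0, n_w),
                rng.uniform(-1.0, 1.0, 1),
                rng.uniform(-0.5, 0.5, 4) if history else [],
                rng.uniform(1.0, 3.0, 1) if selection else [],
            ]
        )
        starts.append(x0)

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "maxiter": 2000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    model = _unpack(best.x, areas, readout_mode, noise_mode, history, selection, lapse, poisson_combine)
    fit = FitResult(
        model=model,
        loglik=float(-best.fun),
        n_restarts=len(starts),
        converged=any_converged,
    )
    fit.implied_noise = implied_noise(fit)
    return fit


def implied_noise(fit: FitResult | ReadoutModel) -> dict[str, dict[str, float]]:
    """Per-task per-area implied representational noise sigma = 1/beta (psc).

    A zero weight implies infinite noise; the sign of the weight is carried
    through so a negative weight yields a negative (anti-correlated) entry.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    out: dict[str, dict[str, float]] = {}
    for task in TASKS:
        out[task] = {}
        for a in model.areas:
            b = model.weights[task][a]
            out[task][a] = float(np.inf) if b == 0.0 else 1.0 / b
    return out


# ---------------------------------------------------------------------------
# analytic JND predictions


def _incremented(base: Stimulus, feature: str, delta: float) -> Stimulus:
    if feature == "contrast":
        return Stimulus(base.contrast + delta, base.coherence)
    return Stimulus(base.contrast, base.coherence + delta)


def _readout_gain(model, prf_set, weights, base, feature):
    """Weighted readout increase as a function of the feature increment."""
    areas = model.areas
    w = np.array([weights[a] for a in areas])
    r0 = np.array([prf_set[a].response(base.contrast, base.coherence) for a in areas])

    def f(delta: float) -> float:
        s = _incremented(base, feature, delta)
        r1 = np.array([prf_set[a].response(s.contrast, s.coherence) for a in areas])
        return float(np.dot(w, r1 - r0))

    return f


def predict_jnd(
    model: ReadoutModel,
    prf_sets,
    task: str,
    base: Stimulus,
    target: float = 1.0,
    *,
    weights_task: str | None = None,
    xtol: float = 1e-8,
) -> float:
    """Analytic JND: increment raising the weighted readout by ``target``.

    With the additive model's unit probit noise, ``target=1`` corresponds to
    d' = 1.  Returns NaN when no increment within the displayable range
    ``(0, 1 - base]`` reaches the target (a non-measurable threshold).
    Raises if the readout is not increasing in the feature at the base.
    """
    by_task = prf_sets_by_task(prf_sets)
    weights = model.weights[weights_task or task]
    f = _readout_gain(model, by_task[task], weights, base, task)

    base_level = base.contrast if task == "contrast" else base.coherence
    max_delta = 1.0 - base_level
    if max_delta <= 0:
        return float("nan")
    eps = min(1e-6, max_delta / 10)
    if f(eps) <= 0:
        raise ValueError(f"readout is not increasing in {task} at base {base_level}")
    if f(max_delta) < target:
        return float("nan")
    return float(brentq(lambda d: f(d) - target, eps, max_delta, xtol=xtol))


def predict_catch_jnd(
    model: ReadoutModel,
    prf_sets,
    task: str,
    base: Stimulus,
    memory_cost: float = 1.0,
    *,
    wrong_readout: bool = True,
    xtol: float = 1e-8,
) -> float:
    """Predicted JND on post-cued catch trials for the judged feature ``task``.

    ``wrong_readout=True`` evaluates the prediction with the *other* task's
    weight set, modelling an observer unable to re-route the readout when the
    post-cue arrives.  ``memory_cost`` scales the required readout difference
    (equivalently the decision noise), modelling the cost of reporting from
    working memory.  NaN means the model predicts the task cannot be done.
    """
    weights_task = _other(task) if wrong_readout else task
    return predict_jnd(
        model, prf_sets, task, base, target=memory_cost, weights_task=weights_task, xtol=xtol
    )


def simulated_jnd(
    model: ReadoutModel,
    prf_sets,
    task: str,
    base: Stimulus,
    criterion: float = PCORRECT_DPRIME1,
    *,
    xtol: float = 1e-8,
) -> float:
    """JND defined on the full choice rule: increment reaching ``criterion``
    percent correct, averaged over which side carries the increment.

    Unlike :func:`predict_jnd` this respects lapse, bias and non-additive
    noise modes, so it is the right notion of threshold for the Poisson and
    selection variants.  Returns NaN when the criterion is unattainable.
    """
    by_task = prf_sets_by_task(prf_sets)
    prf_set = by_task[task]
    w = model.weight_vector(task)
    areas = model.areas

    r_base = np.array([[prf_set[a].response(base.contrast, base.coherence) for a in areas]])

    def p_correct(delta: float) -> float:
        s = _incremented(base, task, delta)
        r_inc = np.array([[prf_set[a].response(s.contrast, s.coherence) for a in areas]])
        p_right_target_right = _block_probability(model, r_base, r_inc, w, None)[0]
        p_right_target_left = _block_probability(model, r_inc, r_base, w, None)[0]
        return 0.5 * (p_right_target_right + (1.0 - p_right_target_left))

    base_level = base.contrast if task == "contrast" else base.coherence
    max_delta = 1.0 - base_level
    if max_delta <= 0 or p_correct(max_delta) < criterion:
        return float("nan")
    return float(brentq(lambda d: p_correct(d) - criterion, 0.0, max_delta, xtol=xtol))
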