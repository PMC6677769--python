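"""Descriptive psychometric fits: cumulative-normal choice curves, Weibull
thresholds (JNDs), lapse estimation, Weber slopes and catch-trial costs.

Thresholds follow the d' = 1 convention for 2AFC: the JND is the stimulus
difference at which percent correct reaches Phi(1/sqrt(2)) ~ 76%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from ._util import as_rng
from .linking import PCORRECT_DPRIME1

__all__ = [
    "CumNormalFit",
    "WeibullFit",
    "JndEstimate",
    "fit_cum_normal",
    "fit_weibull",
    "weibull_jnd",
    "estimate_lapse",
    "weber_slope",
    "catch_cost",
    "signed_differences",
    "session_weibull_fits",
]

_PCLIP = 1e-12


@dataclass
class CumNormalFit:
    """Maximum-likelihood cumulative-normal fit to P(choose right)."""

    mu: float
    sigma: float
    lapse: float
    loglik: float
    r2_pseudo: float
    converged: bool = True
    separated: bool = False

    def predict(self, x):
        return self.lapse / 2.0 + (1.0 - self.lapse) * ndtr((np.asarray(x, float) - self.mu) / self.sigma)


@dataclass
class WeibullFit:
    """Weibull percent-correct fit with guess rate fixed at 0.5 (2AFC)."""

    tau: float
    beta_slope: float
    gamma: float
    lapse: float
    loglik: float
    converged: bool = True
    at_bound: bool = False

    def predict(self, x):
        x = np.maximum(np.asarray(x, float), 0.0)
        return self.gamma + (1.0 - self.gamma - self.lapse) * (
            1.0 - np.exp(-((x / self.tau) ** self.beta_slope))
        )


@dataclass
class JndEstimate:
    task: str
    base_strength: float
    jnd: float
    condition: str = "regular"  # regular | catch | catch_control
    measurable: bool = True


def signed_differences(trials: pd.DataFrame, feature: str) -> np.ndarray:
    """Right-minus-left stimulus difference for one feature."""
    if feature == "contrast":
        return (trials["stim_con_right"] - trials["stim_con_left"]).to_numpy(dtype=float)
    return (trials["stim_coh_right"] - trials["stim_coh_left"]).to_numpy(dtype=float)


def _bernoulli_ll(p, y):
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    return float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def fit_cum_normal(
    trials: pd.DataFrame,
    feature: str | None = None,
    *,
    fit_lapse: bool = True,
    heldout: pd.DataFrame | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> CumNormalFit:
    """Fit mu, sigma (and optionally lapse) to trial-level rightward choices.

    The pseudo-r^2 compares the model's log-likelihood to an intercept-only
    (constant-probability) model, on held-out trials when given, otherwise
    in-sample.  Complete separation is flagged with sigma at its lower bound.
    """
    feature = feature or str(trials["task"].iloc[0])
    x = signed_differences(trials, feature)
    y = (trials["choice"].astype(str) == "right").to_numpy()
    if len(np.unique(np.sign(x))) < 2 or y.all() or (~y).all():
        # not enough structure: fall back to moment-based guesses but still fit
        pass

    bounds = [(-1.0, 1.0), (1e-5, 1.0), (0.0, 0.5) if fit_lapse else (0.0, 0.0)]

    def nll(params):
        mu, sigma, lam = params
        p = lam / 2.0 + (1.0 - lam) * ndtr((x - mu) / sigma)
        return -_bernoulli_ll(p, y)

    rng = as_rng(seed)
    starts = [np.array([0.0, max(np.std(x), 1e-3), 0.02])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array([rng.uniform(-0.1, 0.1), rng.uniform(1e-3, 0.5), rng.uniform(0.0, 0.2) if fit_lapse else 0.0])
        )
    best = None
    conv = False
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=bounds)
        conv = conv or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma, lam = best.x
    separated = sigma <= bounds[1][0] * (1 + 1e-6)

    eval_df = trials if heldout is None else heldout
    xe = signed_differences(eval_df, feature)
    ye = (eval_df["choice"].astype(str) == "right").to_numpy()
    p_model = lam / 2.0 + (1.0 - lam) * ndtr((xe - mu) / sigma)
    ll_model = _bernoulli_ll(p_model, ye)
    p_null = np.clip(np.mean(ye), _PCLIP, 1 - _PCLIP)
    ll_null = _bernoulli_ll(np.full_like(xe, p_null), ye)
    r2 = 0.0 if ll_null == 0 else 1.0 - ll_model / ll_null

    return CumNormalFit(
        mu=float(mu), sigma=float(sigma), lapse=float(lam),
        loglik=float(-best.fun), r2_pseudo=float(r2), converged=conv, separated=separated,
    )


def fit_weibull(
    trials_or_x,
    correct=None,
    *,
    lapse: float = 0.0,
    feature: str | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tau_bounds: tuple[float, float] = (1e-4, 1.0),
    beta_bounds: tuple[float, float] = (0.1, 10.0),
) -> WeibullFit:
    """Maximum-likelihood Weibull fit of percent correct vs cued increment.

    gamma is fixed at 0.5 (2AFC) and the lapse at the given value (estimate
    it first with :func:`estimate_lapse`).  Accepts either a trial table or
    explicit (x, correct) arrays.
    """
    if isinstance(trials_or_x, pd.DataFrame):
        df = trials_or_x
        feature = feature or str(df["task"].iloc[0])
        x = np.abs(signed_differences(df, feature))
        y = df["correct"].to_numpy(dtype=bool)
    else:
        x = np.asarray(trials_or_x, dtype=float)
        y = np.asarray(correct, dtype=bool)
    if len(x) == 0:
        raise ValueError("no trials to fit")
    gamma = 0.5

    def nll(params):
        tau, beta = params
        p = gamma + (1 - gamma - lapse) * (1.0 - np.exp(-((x / tau) ** beta)))
        return -_bernoulli_ll(p, y)

    rng = as_rng(seed)
    x_pos = x[x > 0]
    med = float(np.median(x_pos)) if len(x_pos) else 0.1
    starts = [np.array([np.clip(med, *tau_bounds), 3.0])]
    for _ in range(n_restarts - 1):
        starts.append(np.array([rng.uniform(*tau_bounds), rng.uniform(0.5, 6.0)]))
    best = None
    conv = False
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=[tau_bounds, beta_bounds])
        conv = conv or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    tau, beta = best.x
    at_bound = bool(tau <= tau_bounds[0] * (1 + 1e-6) or tau >= tau_bounds[1] * (1 - 1e-6))
    if not y.any() or y.all():
        at_bound = True
    return WeibullFit(
        tau=float(tau), beta_slope=float(beta), gamma=gamma, lapse=lapse,
        loglik=float(-best.fun), converged=conv, at_bound=at_bound,
    )


def weibull_jnd(fit: WeibullFit, criterion: float = PCORRECT_DPRIME1) -> float:
    """Invert the Weibull at the d'=1 percent-correct criterion (~76%)."""
    top = 1.0 - fit.gamma - fit.lapse
    frac = (criterion - fit.gamma) / top
    if not 0.0 < frac < 1.0:
        return float("nan")
    return float(fit.tau * (-np.log1p(-frac)) ** (1.0 / fit.beta_slope))


def estimate_lapse(
    trials: pd.DataFrame,
    suprathreshold_con: float = 0.15,
    suprathreshold_coh: float = 0.40,
) -> float:
    """Lapse rate from errors on far-suprathreshold trials.

    Under the lapse model the asymptotic error rate is lambda/2, so the
    estimate is twice the error rate on cued increments of at least the
    cutoff (>= 2x threshold), clipped to [0, 1].
    """
    task = trials["task"].astype(str).to_numpy()
    delta = np.where(
        task == "contrast", trials["delta_con"].to_numpy(float), trials["delta_coh"].to_numpy(float)
    )
    cutoff = np.where(task == "contrast", suprathreshold_con, suprathreshold_coh)
    supra = (delta >= cutoff) & ~trials["is_catch"].to_numpy(dtype=bool)
    if not supra.any():
        raise ValueError("no suprathreshold trials; lapse undefined")
    err = 1.0 - trials.loc[supra, "correct"].astype(bool).mean()
    return float(np.clip(2.0 * err, 0.0, 1.0))


def weber_slope(jnds) -> float:
    """Log-log least-squares slope of JND against base strength.

    Accepts a sequence of :class:`JndEstimate` or (base, jnd) pairs; warns
    and excludes non-measurable entries.  Weber's law predicts a slope of 1.
    """
    bases, vals = [], []
    for j in jnds:
        if isinstance(j, JndEstimate):
            if not j.measurable or not np.isfinite(j.jnd):
                warnings.warn(f"excluding non-measurable JND at base {j.base_strength}")
                continue
            bases.append(j.base_strength)
            vals.append(j.jnd)
        else:
            bases.append(j[0])
            vals.append(j[1])
    if len(bases) < 2 or len(set(bases)) < 2:
        raise ValueError("need >=2 measurable JNDs at distinct base strengths")
    lx, ly = np.log(np.asarray(bases)), np.log(np.asarray(vals))
    lx = lx - lx.mean()
    return float(np.dot(lx, ly - ly.mean()) / np.dot(lx, lx))


def catch_cost(jnd_catch: JndEstimate, jnd_control: JndEstimate) -> float:
    """Working-memory cost factor: catch-trial JND over regular-trial JND."""
    if not (jnd_catch.measurable and jnd_control.measurable):
        raise ValueError("catch cost undefined for non-measurable JNDs")
    if jnd_catch.task != jnd_control.task:
        raise ValueError("catch cost requires JNDs from the same task")
    return float(jnd_catch.jnd / jnd_control.jnd)


def session_weibull_fits(trials: pd.DataFrame, lapse: float = 0.0, seed: int = 0):
    """The full per-observer threshold battery for one session.

    Returns (fits, jnds): Weibull fits and JND estimates for (a) regular runs
    at each base strength of the cued feature x 2 tasks, (b) cued trials of
    catch runs (single base) x 2 tasks, and (c) catch trials (post-cued
    feature) x 2 tasks — 12 fits for the standard 4-base session.
    """
    fits: list[WeibullFit] = []
    jnds: list[JndEstimate] = []
    is_catch_run = trials.groupby("run_id")["is_catch"].transform("any")

    def add(df, task, base, condition, feature):
        if len(df) == 0:
            return
        fit = fit_weibull(df, lapse=lapse, feature=feature, seed=seed)
        jnd = weibull_jnd(fit)
        measurable = np.isfinite(jnd) and (fit.tau + base) <= 1.0 and not fit.at_bound
        fits.append(fit)
        jnds.append(JndEstimate(task=task, base_strength=float(base), jnd=float(jnd),
                                condition=condition, measurable=bool(measurable)))

    for task in ("contrast", "coherence"):
        col = "base_con" if task == "contrast" else "base_coh"
        reg = trials[(trials["task"] == task) & ~is_catch_run]
        for base in sorted(reg[col].unique()):
            add(reg[reg[col] == base], task, base, "regular", task)
        cr = trials[(trials["task"] == task) & is_catch_run]
        ctrl = cr[~cr["is_catch"]]
        if len(ctrl):
            base = float(ctrl[col].iloc[0])
            add(ctrl, task, base, "catch_control", task)
        # catch trials judged on the post-cued feature, grouped by that feature
        catch = trials[trials["is_catch"] & (trials["post_cue"] == task)]
        if len(catch):
            base = float(catch[col].iloc[0])
            add(catch, task, base, "catch", task)
    return fits, jnds
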