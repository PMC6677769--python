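"""Event-related BOLD analysis: FIR deconvolution GLM, canonical-HRF
amplitude reduction, and gain/offset fits of the population response
functions across task conditions.

The deconvolution model is y = X b + e where X is a Toeplitz-block design:
each block of k columns belongs to one condition, the first column holds a 1
at every onset volume of that condition and successive columns shift the
indicator down by one volume.  Ordinary least squares on this design yields
each condition's unconstrained k-volume response, accounting linearly for
temporal overlap between events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .response import PopulationResponseFunction, coherence_linear_slope  # noqa: F401
from .synthetic import BoldTimeseries

__all__ = [
    "FirDesign",
    "DeconvolutionResult",
    "build_fir_design",
    "deconvolve",
    "fit_hrf_amplitude",
    "amplitude_table",
    "fit_response_functions",
    "coherence_linear_slope",
    "check_condition_balance",
]


@dataclass
class FirDesign:
    """Toeplitz-block FIR design matrix."""

    matrix: np.ndarray  # (n, k*c) of 0/1
    k: int
    c: int
    n: int
    condition_labels: tuple[str, ...]


@dataclass
class DeconvolutionResult:
    fir_responses: np.ndarray  # (c, k) psc
    residual_variance: float
    design_rank: int
    offdiag_flag: bool
    condition_labels: tuple[str, ...] = ()


def build_fir_design(
    events: pd.DataFrame,
    k: int,
    c: int,
    n: int,
    condition_labels=None,
) -> FirDesign:
    """Build the n x (k*c) FIR design from an event schedule.

    Onsets are 0-based volume indices; responses occupy the half-open window
    [onset, onset+k), truncated at the end of the timeseries (no wraparound).
    """
    onsets = events["onset_volume"].to_numpy(dtype=int)
    conds = events["condition_id"].to_numpy(dtype=int)
    if (onsets < 0).any() or (onsets >= n).any():
        raise ValueError("event onset outside [0, n)")
    if (conds < 0).any() or (conds >= c).any():
        raise ValueError("condition id outside [0, c)")
    x = np.zeros((n, k * c))
    for onset, cond in zip(onsets, conds):
        stop = min(onset + k, n)
        lags = np.arange(stop - onset)
        x[onset + lags, cond * k + lags] += 1.0
    if condition_labels is None:
        if "condition_label" in events.columns:
            by_id = dict(zip(conds, events["condition_label"]))
            condition_labels = tuple(by_id.get(i, f"cond{i}") for i in range(c))
        else:
            condition_labels = tuple(f"cond{i}" for i in range(c))
    return FirDesign(matrix=x, k=k, c=c, n=n, condition_labels=tuple(condition_labels))


def deconvolve(y, design: FirDesign) -> DeconvolutionResult:
    """OLS estimate of per-condition FIR responses.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning and set the diagnostics flag.
    """
    values = y.values if isinstance(y, BoldTimeseries) else np.asarray(y, dtype=float)
    if len(values) != design.n:
        raise ValueError(f"timeseries length {len(values)} != design n {design.n}")
    x = design.matrix
    beta, _, rank, _ = np.linalg.lstsq(x, values, rcond=None)
    full_rank = rank == x.shape[1]
    if not full_rank:
        warnings.warn("rank-deficient FIR design; using minimum-norm solution")
    resid = values - x @ beta
    dof = max(design.n - rank, 1)
    gram = x.T @ x
    diag = np.diag(gram)
    off = gram[~np.eye(len(gram), dtype=bool)]
    thresh = 0.10 * np.median(diag[diag > 0]) if (diag > 0).any() else 0.0
    frac_large = float(np.mean(np.abs(off) > thresh)) if len(off) else 0.0
    return DeconvolutionResult(
        fir_responses=beta.reshape(design.c, design.k),
        residual_variance=float(resid @ resid / dof),
        design_rank=int(rank),
        offdiag_flag=bool(not full_rank or frac_large > 1e-3),
        condition_labels=design.condition_labels,
    )


def fit_hrf_amplitude(fir_response, canonical_hrf) -> float:
    """Least-squares scalar scaling the canonical HRF to one FIR response.

    Closed form <fir, hrf> / <hrf, hrf>; the kernel must be peak-normalized
    so the scalar is in percent signal change.
    """
    fir = np.asarray(fir_response, dtype=float)
    hrf = np.asarray(canonical_hrf, dtype=float)
    m = min(len(fir), len(hrf))
    fir, hrf = fir[:m], hrf[:m]
    denom = float(hrf @ hrf)
    if denom == 0.0:
        raise ValueError("all-zero HRF kernel")
    return float(fir @ hrf / denom)


def amplitude_table(
    result: DeconvolutionResult,
    canonical_hrf,
    base_contrasts,
    base_coherences,
) -> pd.DataFrame:
    """Reduce FIR responses to one scalar per (base_con, base_coh, task).

    Condition ids are assumed task-major then contrast-major then coherence,
    the ordering emitted by the synthetic scan schedule.
    """
    n_con, n_coh = len(base_contrasts), len(base_coherences)
    if result.fir_responses.shape[0] != 2 * n_con * n_coh:
        raise ValueError("condition count does not match the base grids x 2 tasks")
    rows = []
    i = 0
    for task in ("contrast", "coherence"):
        for bc in base_contrasts:
            for bh in base_coherences:
                rows.append(
                    {
                        "task": task,
                        "base_con": float(bc),
                        "base_coh": float(bh),
                        "amplitude": fit_hrf_amplitude(result.fir_responses[i], canonical_hrf),
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def fit_response_functions(
    amps: pd.DataFrame,
    init_prf: PopulationResponseFunction,
    area: str | None = None,
) -> dict[str, PopulationResponseFunction]:
    """Per-task gain/offset fit of the population response functions.

    For each task the free parameters are (alpha_con, alpha_coh, alpha_task)
    while sigma_con and kappa are held at their passive-viewing values so the
    response functions keep their shape — six free parameters per area in
    total.  With the shapes fixed the model is linear in the free
    parameters, so the least-squares solution is exact.
    """
    out = {}
    for task in ("contrast", "coherence"):
        sub = amps[amps["task"] == task]
        if sub[["base_con", "base_coh"]].drop_duplicates().shape[0] < 3:
            raise ValueError(f"need >=3 distinct base cells per task, task {task!r}")
        shape = PopulationResponseFunction(
            area=init_prf.area, alpha_con=1.0, sigma_con=init_prf.sigma_con,
            alpha_coh=1.0, kappa=init_prf.kappa,
        )
        g = shape.contrast_response(sub["base_con"].to_numpy())
        h = shape.coherence_response(sub["base_coh"].to_numpy())
        design = np.column_stack([g, h, np.ones(len(sub))])
        coef, *_ = np.linalg.lstsq(design, sub["amplitude"].to_numpy(), rcond=None)
        out[task] = PopulationResponseFunction(
            area=area or init_prf.area,
            alpha_con=float(coef[0]),
            sigma_con=init_prf.sigma_con,
            alpha_coh=float(coef[1]),
            kappa=init_prf.kappa,
            alpha_task=float(coef[2]),
        )
    return out


def check_condition_balance(events: pd.DataFrame) -> pd.DataFrame:
    """Chi-square test of each condition's follower distribution vs uniform.

    A balanced randomized schedule should give large p-values for every row;
    rows with too few transitions get NaN and a flag.
    """
    conds = events["condition_id"].to_numpy(dtype=int)
    if len(np.unique(conds)) < 2:
        raise ValueError("need >=2 conditions to assess balance")
    ids = np.unique(conds)
    idx = {c: i for i, c in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)))
    for a, b in zip(conds[:-1], conds[1:]):
        counts[idx[a], idx[b]] += 1
    rows = []
    for i, c in enumerate(ids):
        row = counts[i]
        total = row.sum()
        if total < 2 * len(ids):
            rows.append({"condition_id": int(c), "n_transitions": int(total), "p_value": np.nan, "flagged": True})
            continue
        stat, p = chisquare(row)
        rows.append({"condition_id": int(c), "n_transitions": int(total), "p_value": float(p), "flagged": False})
    return pd.DataFrame(rows)
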