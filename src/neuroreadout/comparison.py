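"""Cross-validated model comparison and Tjur's coefficient of discrimination.

Models are compared by the summed held-out Bernoulli log-likelihood over a
k-fold partition (natural log throughout).  A difference (log-likelihood
ratio) above ~10 nats is conventionally treated as a substantial improvement;
cross-validation already penalizes extra parameters, so no AIC/BIC-style
correction is applied.  Tjur's coefficient of discrimination

    CD = mean P(right | chose right) - mean P(right | chose left)

summarizes how well the trial-by-trial predictions separate the two choice
classes (1 = perfect, 0 = chance); here it is computed on held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._util import as_rng
from .linking import bernoulli_loglik

__all__ = ["ModelComparisonResult", "make_folds", "crossval_loglik", "loglik_ratio", "tjur_cd"]


@dataclass
class ModelComparisonResult:
    model_label: str
    fold_logliks: list[float]
    total_cv_loglik: float
    cd: float
    n_folds: int
    fold_seed: int
    n_trials: int = 0
    predictions: np.ndarray | None = field(default=None, repr=False)


def make_folds(
    trials: pd.DataFrame,
    n_folds: int,
    seed: int,
    stratify_by=("task",),
) -> np.ndarray:
    """Deterministic random fold labels, stratified so each fold sees every
    stratum (by default, both tasks)."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = as_rng(seed)
    labels = np.empty(len(trials), dtype=int)
    if stratify_by:
        strata = trials.groupby(list(stratify_by), sort=True, observed=True).indices
    else:
        strata = {"all": np.arange(len(trials))}
    for _, idx in sorted(strata.items(), key=lambda kv: str(kv[0])):
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        labels[idx[perm]] = np.arange(len(idx)) % n_folds
    return labels


def crossval_loglik(
    trials: pd.DataFrame,
    model_label: str,
    fit_fn: Callable[[pd.DataFrame], object],
    predict_fn: Callable[[object, pd.DataFrame], np.ndarray],
    n_folds: int = 10,
    seed: int = 0,
    stratify_by=("task",),
) -> ModelComparisonResult:
    """k-fold cross-validated log-likelihood of a choice model.

    ``fit_fn(train)`` returns a fitted object; ``predict_fn(fitted, test)``
    returns per-trial P(choose right).  Held-out predictions are pooled to
    compute the cross-validated Tjur CD.
    """
    folds = make_folds(trials, n_folds, seed, stratify_by)
    y = (trials["choice"].astype(str) == "right").to_numpy()
    fold_lls: list[float] = []
    pooled = np.empty(len(trials))
    for f in range(n_folds):
        test = folds == f
        train_df = trials.loc[~test]
        test_df = trials.loc[test]
        if len(train_df) == 0 or len(test_df) == 0:
            raise ValueError(f"fold {f} is empty; too few trials for {n_folds} folds")
        try:
            fitted = fit_fn(train_df)
        except Exception as err:  # re-raise naming the fold
            raise RuntimeError(f"fit failed on fold {f}: {err}") from err
        p = np.asarray(predict_fn(fitted, test_df), dtype=float)
        pooled[test] = p
        fold_lls.append(bernoulli_loglik(p, y[test]))
    return ModelComparisonResult(
        model_label=model_label,
        fold_logliks=fold_lls,
        total_cv_loglik=float(np.sum(fold_lls)),
        cd=tjur_cd(pooled, y),
        n_folds=n_folds,
        fold_seed=seed,
        n_trials=len(trials),
        predictions=pooled,
    )


def loglik_ratio(a: ModelComparisonResult, b: ModelComparisonResult) -> float:
    """Difference in total cross-validated log-likelihood, a minus b (nats)."""
    if (a.n_folds, a.fold_seed, a.n_trials) != (b.n_folds, b.fold_seed, b.n_trials):
        raise ValueError("results come from different fold partitions")
    return float(a.total_cv_loglik - b.total_cv_loglik)


def tjur_cd(predicted_p_right, choices) -> float:
    """Tjur's coefficient of discrimination for binary choice predictions.

    ``choices`` may be booleans (True = right) or "left"/"right" labels.
    """
    p = np.asarray(predicted_p_right, dtype=float)
    c = np.asarray(choices)
    if c.dtype.kind in ("U", "S", "O"):
        c = np.asarray([str(v) == "right" for v in c])
    c = c.astype(bool)
    if c.all() or (~c).all():
        raise ValueError("both choice classes must be present to compute CD")
    return float(p[c].mean() - p[~c].mean())
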