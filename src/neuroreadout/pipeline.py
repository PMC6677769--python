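"""End-to-end orchestration: config parsing and seeded simulate-fit-compare
runs with serialized, re-runnable intermediates."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from ._util import derive_seed
from .comparison import crossval_loglik, loglik_ratio
from .linking import ReadoutModel, choice_probabilities, fit_readout
from .psychophysics import estimate_lapse, fit_cum_normal, session_weibull_fits, weber_slope
from .response import default_prf_set
from .stimuli import write_trials
from .synthetic import ConfigError, TaskConfig, simulate_behavioral_session

logger = logging.getLogger("neuroreadout")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "default_truth"]

_DEFAULT_AREAS = ("V1", "MT")
# Ground-truth readout weights for the two-area demo observer.  Scaled so the
# analytic JNDs land in the measured range (a few percent contrast at the
# lowest base; ~15% coherence): the weight is roughly 1 / (response-function
# slope x threshold increment) for the task-relevant area.
_DEFAULT_TRUTH_WEIGHTS = {
    "contrast": {"V1": 13.0, "MT": 1.0},
    "coherence": {"V1": 1.0, "MT": 21.0},
}


@dataclass
class PipelineConfig:
    seed: int = 1
    task: TaskConfig = field(default_factory=TaskConfig)
    truth: dict = field(default_factory=dict)
    prf: dict = field(default_factory=lambda: {"areas": list(_DEFAULT_AREAS), "sigma_con": 0.5, "kappa": 1.0})
    fitting: dict = field(default_factory=lambda: {"n_restarts": 4})
    comparison: dict = field(default_factory=lambda: {"n_folds": 10})
    variants: list = field(default_factory=lambda: ["flexible", "fixed"])
    output_dir: str = "neuroreadout_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = self.task.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        # output_dir is plumbing, not part of the scientific configuration
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


_KNOWN_VARIANTS = {"flexible", "fixed", "poisson", "history", "selection"}
_TOP_KEYS = {"seed", "task", "truth", "prf", "fitting", "comparison", "variants", "output_dir"}


def default_truth(areas=_DEFAULT_AREAS, lapse: float = 0.03) -> ReadoutModel:
    """Two-area flexible ground-truth observer used by the demo pipeline."""
    weights = {t: {a: _DEFAULT_TRUTH_WEIGHTS[t].get(a, 1.0) for a in areas} for t in ("contrast", "coherence")}
    return ReadoutModel(
        areas=tuple(areas), weights=weights, beta_bias=0.1, lapse=lapse, readout_mode="flexible"
    )


def validate_config(raw) -> PipelineConfig:
    """Build a validated PipelineConfig from YAML text, a path, or a mapping.

    Missing sections get the study defaults; unknown keys are rejected with
    their path.  An empty document yields the full default configuration.
    """
    if isinstance(raw, (str, Path)) and str(raw) and "\n" not in str(raw) and Path(str(raw)).is_file():
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    task_raw = dict(raw.get("task", {}))
    known_task = {f.name for f in dataclasses.fields(TaskConfig)}
    unknown = set(task_raw) - known_task
    if unknown:
        raise ConfigError(f"unknown task key(s): {sorted('task.' + k for k in unknown)}")
    task = TaskConfig.from_dict(task_raw)

    variants = list(raw.get("variants", ["flexible", "fixed"]))
    bad = set(variants) - _KNOWN_VARIANTS
    if bad:
        raise ConfigError(f"unknown variant(s): {sorted(bad)}")

    cfg = PipelineConfig(
        seed=int(raw.get("seed", 1)),
        task=task,
        truth=dict(raw.get("truth", {})),
        prf={**{"areas": list(_DEFAULT_AREAS), "sigma_con": 0.5, "kappa": 1.0}, **dict(raw.get("prf", {}))},
        fitting={**{"n_restarts": 4}, **dict(raw.get("fitting", {}))},
        comparison={**{"n_folds": 10}, **dict(raw.get("comparison", {}))},
        variants=variants,
        output_dir=str(raw.get("output_dir", "neuroreadout_out")),
    )
    return cfg


def _variant_spec(name: str) -> dict:
    return {
        "flexible": dict(readout_mode="flexible"),
        "fixed": dict(readout_mode="fixed"),
        "poisson": dict(readout_mode="flexible", noise_mode="poisson"),
        "history": dict(readout_mode="flexible", history=True),
        "selection": dict(readout_mode="flexible", selection=True),
    }[name]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate-behavior -> fit-psychometric -> fit-linking -> compare-models.

    Writes trials.csv, fits.json, comparison.json and report.json under
    ``cfg.output_dir``; returns the report dict.  Each stage draws its
    randomness from a stream named after the stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash, "stages": {}}

    def stage(name):
        logger.info("stage=%s seed=%s elapsed=%.1fs", name, cfg.seed, time.time() - t0)

    try:
        stage("simulate-behavior")
        areas = tuple(cfg.prf["areas"])
        prf_set = default_prf_set(areas, sigma_con=cfg.prf["sigma_con"], kappa=cfg.prf["kappa"])
        if cfg.truth:
            truth = ReadoutModel.from_dict(cfg.truth)
        else:
            truth = default_truth(areas)
        trials = simulate_behavioral_session(cfg.task, truth, prf_set, seed=derive_seed(cfg.seed, "behavior"))
        write_trials(trials, out / "trials.csv")
        report["stages"]["simulate_behavior"] = {"n_trials": len(trials)}

        stage("fit-psychometric")
        try:
            lapse = estimate_lapse(trials)
        except ValueError:
            lapse = truth.lapse
        psycho = {"lapse": lapse, "cum_normal": {}, "weibull": []}
        for task in ("contrast", "coherence"):
            sub = trials[(trials["task"] == task) & ~trials["is_catch"]]
            fit = fit_cum_normal(sub, feature=task, seed=derive_seed(cfg.seed, "cumnormal"))
            psycho["cum_normal"][task] = dataclasses.asdict(fit)
        fits, jnds = session_weibull_fits(trials, lapse=lapse, seed=derive_seed(cfg.seed, "weibull"))
        psycho["weibull"] = [
            {**dataclasses.asdict(f), **dataclasses.asdict(j)} for f, j in zip(fits, jnds)
        ]
        for task in ("contrast", "coherence"):
            sel = [j for j in jnds if j.task == task and j.condition == "regular" and j.measurable]
            if len(sel) >= 2:
                psycho[f"weber_slope_{task}"] = weber_slope(sel)
        (out / "fits.json").write_text(json.dumps(psycho, indent=1, default=float))
        report["stages"]["fit_psychometric"] = {"lapse": lapse, "n_weibull_fits": len(fits)}

        stage("fit-linking")
        fit_kwargs = dict(cfg.fitting)
        n_restarts = int(fit_kwargs.pop("n_restarts", 4))
        fit_trials = trials[~trials["is_catch"]]
        results = {}
        for name in cfg.variants:
            spec = _variant_spec(name)
            res = crossval_loglik(
                fit_trials,
                model_label=name,
                fit_fn=lambda tr, spec=spec: fit_readout(
                    tr, prf_set, lapse=lapse, n_restarts=n_restarts,
                    seed=derive_seed(cfg.seed, "fit"), **spec, **fit_kwargs,
                ),
                predict_fn=lambda fit, te: choice_probabilities(fit.model, prf_set, te),
                n_folds=int(cfg.comparison["n_folds"]),
                seed=derive_seed(cfg.seed, "folds"),
            )
            results[name] = res
        stage("compare-models")
        comparison = {
            name: {
                "fold_logliks": r.fold_logliks,
                "total_cv_loglik": r.total_cv_loglik,
                "cd": r.cd,
                "n_folds": r.n_folds,
            }
            for name, r in results.items()
        }
        comparison["ratios"] = {
            f"{a}_vs_{b}": loglik_ratio(results[a], results[b])
            for a in results for b in results if a != b
        }
        (out / "comparison.json").write_text(json.dumps(comparison, indent=1, default=float))
        report["stages"]["compare_models"] = comparison
    except Exception as err:
        report["error"] = str(err)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        raise

    # wall time goes to the log only, so report.json is byte-identical
    # across repeated runs of the same config + seed
    logger.info("stage=done seed=%s elapsed=%.1fs", cfg.seed, time.time() - t0)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float, sort_keys=True))
    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:12] for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
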