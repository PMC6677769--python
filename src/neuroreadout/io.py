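"""JSON serialization for response-function sets and readout models.

Both formats round-trip losslessly: floats are written at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

from .linking import ReadoutModel, TASKS
from .response import PopulationResponseFunction

__all__ = ["save_prf_sets", "load_prf_sets", "save_model", "load_model"]


def _prf_set_to_dict(prf_set):
    return {a: prf.to_dict() for a, prf in prf_set.items()}


def _prf_set_from_dict(d):
    return {a: PopulationResponseFunction.from_dict(v) for a, v in d.items()}


def save_prf_sets(prf_sets, path) -> None:
    """Write a PRF set (shared, {area: prf}) or per-task ({task: {area: prf}})."""
    if set(prf_sets) == set(TASKS):
        payload = {"per_task": True, "sets": {t: _prf_set_to_dict(prf_sets[t]) for t in TASKS}}
    else:
        payload = {"per_task": False, "sets": _prf_set_to_dict(prf_sets)}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_prf_sets(path):
    payload = json.loads(Path(path).read_text())
    if payload["per_task"]:
        return {t: _prf_set_from_dict(payload["sets"][t]) for t in TASKS}
    return _prf_set_from_dict(payload["sets"])


def save_model(model: ReadoutModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> ReadoutModel:
    return ReadoutModel.from_dict(json.loads(Path(path).read_text()))
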