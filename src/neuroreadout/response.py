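"""Population response functions of visual cortical areas.

Each area's mean BOLD response (percent signal change) to a dot patch is
modelled as the sum of a Naka–Rushton contrast component, a saturating
exponential coherence component, and an additive task offset:

    R_con(s)  = alpha_con * s**1.9 / (s**1.6 + sigma_con**1.6)
    R_coh(s)  = alpha_coh * (1 - exp(-s / kappa))
    R(s_con, s_coh) = R_con(s_con) + R_coh(s_coh) + alpha_task

The exponent of the coherence component is negative so that the function
saturates and ``kappa`` marks the point where it reaches 63% (1 - 1/e) of its
asymptote ``alpha_coh``.  Amplitudes are in percent signal change; stimulus
strengths are proportions in [0, 1].

Because ``alpha_coh`` and ``kappa`` trade off in the near-linear regime, the
field reports coherence sensitivity as the least-squares *linear slope* of
the coherence component over [0, 1]; see :func:`coherence_linear_slope`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np

from .stimuli import Stimulus

__all__ = [
    "PopulationResponseFunction",
    "AREAS",
    "area_response",
    "readout_response",
    "coherence_linear_slope",
    "alpha_coh_for_slope",
    "default_prf_set",
]

#: Visual areas, ordered from early to late.
AREAS = ("V1", "V2", "V3", "V4", "V3A", "V3B", "V7", "MT")

# Naka-Rushton exponents (fixed across areas).
EXP_NUM = 1.9
EXP_DEN = 1.6

# Passive-viewing contrast amplitudes (psc) per area.
_DEFAULT_ALPHA_CON = {
    "V1": 1.68, "V2": 0.69, "V3": 0.63, "V4": 0.61,
    "V3A": 0.35, "V3B": 0.24, "V7": 0.32, "MT": 0.22,
}
# Passive-viewing coherence sensitivity as linear slope (psc / unit coherence).
_DEFAULT_COH_SLOPE = {
    "V1": 0.07, "V2": 0.16, "V3": 0.18, "V4": 0.11,
    "V3A": 0.25, "V3B": 0.14, "V7": 0.20, "MT": 0.34,
}


@dataclass
class PopulationResponseFunction:
    """Parameterized response of one cortical area to contrast and coherence."""

    area: str
    alpha_con: float
    sigma_con: float
    alpha_coh: float
    kappa: float
    alpha_task: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_con <= 0 or self.kappa <= 0:
            raise ValueError("sigma_con and kappa must be positive")

    def contrast_response(self, s_con):
        s = np.asarray(s_con, dtype=float)
        return self.alpha_con * s**EXP_NUM / (s**EXP_DEN + self.sigma_con**EXP_DEN)

    def coherence_response(self, s_coh):
        s = np.asarray(s_coh, dtype=float)
        return self.alpha_coh * (1.0 - np.exp(-s / self.kappa))

    def response(self, s_con, s_coh):
        return self.contrast_response(s_con) + self.coherence_response(s_coh) + self.alpha_task

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationResponseFunction":
        return cls(**dict(d))


def area_response(prf: PopulationResponseFunction, s: Stimulus) -> float:
    """Mean response of one area to one dot patch (percent signal change)."""
    return float(prf.response(s.contrast, s.coherence))


def readout_response(
    prf_set: Mapping[str, PopulationResponseFunction],
    weights: Mapping[str, float],
    s: Stimulus,
) -> float:
    """Weighted sum of area responses: the scalar readout for one patch."""
    missing = [a for a in prf_set if a not in weights]
    if missing:
        raise KeyError(f"missing readout weight for area(s): {missing}")
    return float(sum(weights[a] * area_response(prf, s) for a, prf in prf_set.items()))


def coherence_linear_slope(prf: PopulationResponseFunction, n_grid: int = 101) -> float:
    """Least-squares linear slope of the coherence component on [0, 1].

    Evaluated on ``n_grid`` evenly spaced points; psc per unit coherence.
    """
    s = np.linspace(0.0, 1.0, n_grid)
    r = prf.coherence_response(s)
    sc = s - s.mean()
    return float(np.dot(sc, r - r.mean()) / np.dot(sc, sc))


def alpha_coh_for_slope(slope: float, kappa: float, n_grid: int = 101) -> float:
    """Amplitude giving a target linear slope at the given saturation constant.

    The slope is proportional to ``alpha_coh``, so this is a single division.
    """
    unit = coherence_linear_slope(
        PopulationResponseFunction("_", 0.0, 1.0, 1.0, kappa), n_grid=n_grid
    )
    return float(slope / unit)


def default_prf_set(
    areas: Iterable[str] = AREAS,
    sigma_con: float = 0.5,
    kappa: float = 1.0,
    alpha_task: float = 0.0,
) -> dict[str, PopulationResponseFunction]:
    """Per-area response functions from group passive-viewing sensitivities.

    Contrast amplitudes are taken directly from the published group values;
    coherence amplitudes are backed out from the published linear slopes at
    the given ``kappa`` (the near-linear regime, the published regime for
    these areas).  ``sigma_con`` is shared across areas.
    """
    out = {}
    for a in areas:
        if a not in _DEFAULT_ALPHA_CON:
            raise KeyError(f"unknown area {a!r}; known: {AREAS}")
        out[a] = PopulationResponseFunction(
            area=a,
            alpha_con=_DEFAULT_ALPHA_CON[a],
            sigma_con=sigma_con,
            alpha_coh=alpha_coh_for_slope(_DEFAULT_COH_SLOPE[a], kappa),
            kappa=kappa,
            alpha_task=alpha_task,
        )
    return out
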