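"""PEST adaptive staircase (parameter estimation by sequential testing).

The staircase holds the stimulus increment at a level until a Wald
sequential test decides performance is reliably above or below the target
probability, then steps the level down or up.  Step sizes follow the classic
heuristics: halve on every reversal, keep the size on the second step in a
direction, double from the third successive same-direction step onward —
except that when the step immediately preceding the most recent reversal was
itself a doubled step, doubling waits for the fourth step.

Levels are stimulus increments (proportions); larger levels are easier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._util import as_rng

__all__ = ["PestStaircase", "StaircaseState", "WeibullObserver", "run_pest_staircase"]


@dataclass
class StaircaseState:
    """Full trace of one staircase run."""

    levels: list[float] = field(default_factory=list)
    outcomes: list[bool] = field(default_factory=list)
    steps: list[float] = field(default_factory=list)
    reversals: int = 0
    diverged: bool = False

    @property
    def history(self) -> list[tuple[float, bool]]:
        return list(zip(self.levels, self.outcomes))


class PestStaircase:
    """Classic PEST controller for one (task, base strength) condition."""

    def __init__(
        self,
        initial_level: float,
        initial_step: float | None = None,
        target: float = 0.82,
        wald: float = 1.0,
        min_step: float = 1e-3,
        max_step: float = 0.2,
        bounds: tuple[float, float] = (1e-4, 1.0),
    ):
        if not 0.0 < target < 1.0:
            raise ValueError("target must be a probability in (0, 1)")
        if bounds[0] >= bounds[1]:
            raise ValueError("staircase bounds inverted")
        self.target = target
        self.wald = wald
        self.min_step = min_step
        self.max_step = max_step
        self.bounds = bounds
        self.level = float(np.clip(initial_level, *bounds))
        self.step = initial_step if initial_step is not None else self.level / 2.0
        self.step = float(np.clip(self.step, min_step, max_step))
        # run bookkeeping at the current level
        self._n = 0
        self._k = 0
        # step-rule bookkeeping
        self._direction = 0  # -1 down (harder), +1 up (easier)
        self._same_count = 0
        self._last_was_double = False
        self._double_before_reversal = False
        self.state = StaircaseState()
        self._at_upper = 0

    def update(self, correct: bool) -> None:
        """Record one trial at the current level and step if the Wald test trips."""
        self.state.levels.append(self.level)
        self.state.outcomes.append(bool(correct))
        self.state.steps.append(self.step)
        self._n += 1
        self._k += int(correct)
        expected = self.target * self._n
        if self._k >= expected + self.wald:
            self._move(-1)  # above target: make it harder
        elif self._k <= expected - self.wald:
            self._move(+1)  # below target: make it easier

    def _move(self, direction: int) -> None:
        if direction == self._direction:
            self._same_count += 1
            need = 4 if self._double_before_reversal else 3
            if self._same_count >= need:
                self.step *= 2.0
                self._last_was_double = True
            else:
                self._last_was_double = False
        else:
            if self._direction != 0:
                self.state.reversals += 1
                self._double_before_reversal = self._last_was_double
                self.step /= 2.0
            self._same_count = 1
            self._last_was_double = False
            self._direction = direction
        self.step = float(np.clip(self.step, self.min_step, self.max_step))
        self.level = float(np.clip(self.level + direction * self.step, *self.bounds))
        self._at_upper = self._at_upper + 1 if self.level >= self.bounds[1] else 0
        if self._at_upper >= 5:
            self.state.diverged = True
        self._n = 0
        self._k = 0

    def reset_step(self, fraction: float = 1.0 / 3.0) -> None:
        """Periodic step reset to a fraction of the current level, to track
        slow threshold drift across sessions."""
        self.step = float(np.clip(fraction * self.level, self.min_step, self.max_step))
        self._same_count = 0
        self._last_was_double = False
        self._double_before_reversal = False


@dataclass
class WeibullObserver:
    """Synthetic 2AFC observer with a Weibull psychometric function.

    P(correct | x) = gamma + (1 - gamma - lapse) * (1 - exp(-(x/tau)**beta))
    """

    tau: float
    beta: float
    gamma: float = 0.5
    lapse: float = 0.0

    def p_correct(self, x: float) -> float:
        x = max(float(x), 0.0)
        return self.gamma + (1.0 - self.gamma - self.lapse) * (1.0 - np.exp(-((x / self.tau) ** self.beta)))

    __call__ = p_correct


def run_pest_staircase(
    observer: Callable[[float], float],
    n_trials: int,
    seed,
    *,
    base_level: float = 0.0,
    initial_level: float = 0.25,
    initial_step: float | None = None,
    target: float = 0.82,
    step_reset_every: int | None = None,
    **pest_kwargs,
) -> StaircaseState:
    """Run a PEST staircase against an observer.

    ``observer`` maps an increment level to P(correct).  ``base_level``
    caps displayable increments at ``1 - base_level``.  If
    ``step_reset_every`` is given, the step is reset to one third of the
    current level every that many trials (session-boundary behaviour).
    Returns the full level/outcome trace.
    """
    rng = as_rng(seed)
    upper = max(1e-3, 1.0 - base_level)
    bounds = pest_kwargs.pop("bounds", (1e-4, upper))
    stair = PestStaircase(
        initial_level=min(initial_level, upper),
        initial_step=initial_step,
        target=target,
        bounds=bounds,
        **pest_kwargs,
    )
    for i in range(n_trials):
        if step_reset_every and i > 0 and i % step_reset_every == 0:
            stair.reset_step()
        p = float(observer(stair.level))
        stair.update(rng.random() < p)
    return stair.state
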