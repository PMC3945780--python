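"""Right-continuous step functions on a time grid.

Survival and cumulative-hazard estimators are step functions that jump at
event times; IPCW weights additionally need left limits ``f(t-)``.  The
container keeps the jump grid and post-jump values and evaluates both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """``f(t) = init`` for ``t < times[0]``, then ``values[k]`` for
    ``times[k] <= t < times[k+1]`` (right-continuous)."""

    times: np.ndarray
    values: np.ndarray
    init: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray:
        """Evaluate ``f(t)`` (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return np.where(idx == 0, self.init,
                        np.concatenate(([self.init], self.values))[idx])

    def left(self, t) -> np.ndarray:
        """Evaluate the left limit ``f(t-)``."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        return np.where(idx == 0, self.init,
                        np.concatenate(([self.init], self.values))[idx])
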