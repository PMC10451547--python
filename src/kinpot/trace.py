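"""The central I/O object: a measured potential trace E(t)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

__all__ = ["PotentialTrace"]


@dataclass
class PotentialTrace:
    """Potential vs time with an annotated antioxidant-addition time.

    Attributes
    ----------
    t : array
        Strictly increasing time grid, s.
    e : array
        Measured potential, V.
    t_add : float
        Time at which the antioxidant was introduced, s; must lie
        within ``[t[0], t[-1])``.
    meta : dict
        Free-form metadata (temperature, seed, generating truth, ...).
    """

    t: np.ndarray
    e: np.ndarray
    t_add: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2 or self.t.shape != self.e.shape:
            raise InputError("trace needs matching 1-D t and e with >= 2 points")
        bad = np.where(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise InputError(
                f"time grid not strictly increasing at sample index {bad[0] + 1}"
            )
        if not (self.t[0] <= self.t_add < self.t[-1]):
            raise InputError(
                f"t_add={self.t_add} s outside trace span [{self.t[0]}, {self.t[-1]}) s"
            )

    @property
    def dt_median(self) -> float:
        return float(np.median(np.diff(self.t)))

    def baseline(self, window: float = 30.0) -> float:
        """Mean potential over the ``window`` seconds preceding ``t_add``."""
        mask = (self.t >= self.t_add - window) & (self.t <= self.t_add)
        if not mask.any():
            raise InputError("no samples in the pre-addition baseline window")
        return float(self.e[mask].mean())
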