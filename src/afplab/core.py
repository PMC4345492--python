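"""Shared time-series container for force signals."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class ForceTrace:
    """A uniformly (or near-uniformly) sampled force-versus-time signal.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    force : ndarray, shape (n,)
        Vertical force in newtons at each sample time.
    meta : dict
        Free-form provenance (generating spec, seed, processing history) so
        downstream parameter-recovery checks can compare against stated truth.
    """

    time: np.ndarray
    force: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.ndim != 1 or self.force.shape != self.time.shape:
            raise ValueError("time and force must be 1-D arrays of equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        if self.time.size < 2:
            raise ValueError("trace too short to define a sampling interval")
        return float(np.median(np.diff(self.time)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def resample(self, dt: float) -> "ForceTrace":
        """Linear-interpolation resample onto a uniform grid with step ``dt``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        n = int(np.floor(self.duration / dt)) + 1
        t = self.time[0] + dt * np.arange(n)
        return ForceTrace(t, np.interp(t, self.time, self.force), dict(self.meta))

    def with_force(self, force: np.ndarray, **meta: Any) -> "ForceTrace":
        """Copy of this trace with a new force array and updated metadata."""
        merged = dict(self.meta)
        merged.update(meta)
        return ForceTrace(self.time.copy(), np.asarray(force, dtype=float), merged)

    def __len__(self) -> int:
        return self.time.size
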