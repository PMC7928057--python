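"""Uniformly sampled force time series shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForceTrace"]


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled force signal for one motor channel.

    Parameters
    ----------
    sample_rate : float
        Sampling rate in Hz (> 0).
    values : array-like of float
        Force samples in newtons; must be finite and contain >= 2 samples.
    t0 : float
        Time of the first sample in seconds (onset of recording).
    """

    sample_rate: float
    values: np.ndarray = field(repr=False)
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("trace needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace values must be finite")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be positive")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Time spanned between first and last sample, seconds."""
        return (self.values.size - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def shifted(self, dt_s: float) -> "ForceTrace":
        """Same samples with the time origin moved by ``dt_s`` seconds."""
        return ForceTrace(self.sample_rate, self.values.copy(), self.t0 + dt_s)
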