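"""Stimulus construction: raised-cosine force pulses, lagged vertical /
horizontal pulse pairs, and the pseudo-random trial schedule.

The stimulus is a single non-negative sinusoidal bump — the wires pulling the
skin tabs can only pull, so a full sine cycle (which goes negative) is not
realizable.  A raised cosine of one period at the pulse frequency is
sinusoidal, non-negative, and has the nominal ~167 ms duration at 6 Hz.

Sign convention for lags: positive lag means the *vertical* pulse starts
before the horizontal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .traces import ForceTrace

__all__ = [
    "DESIGN_LAGS_MS",
    "PulseSpec",
    "TrialSchedule",
    "make_pulse",
    "make_lagged_pair",
    "schedule_trials",
]

#: The 14 signed time-lag conditions (ms) of the full design.
DESIGN_LAGS_MS: tuple[int, ...] = (
    -120, -100, -80, -60, -40, -20, -10, 10, 20, 40, 60, 80, 100, 120,
)


@dataclass(frozen=True)
class PulseSpec:
    """Parameters of a single raised-cosine force pulse.

    ``frequency`` (Hz) sets the pulse duration to one period; ``peak`` (N) is
    the maximum force; ``pre_silence`` / ``post_silence`` (s) pad the pulse
    with zeros so that lag shifts and onset detection have headroom.
    """

    frequency: float = 6.0
    peak: float = 2.0
    sample_rate: float = 100.0
    pre_silence: float = 0.2
    post_silence: float = 0.3

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.peak <= 0:
            raise ValueError("peak must be positive")
        if self.sample_rate < 2 * self.frequency:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz is below the Nyquist "
                f"limit 2 x {self.frequency} Hz"
            )
        if self.pre_silence < 0 or self.post_silence < 0:
            raise ValueError("silence padding must be non-negative")

    @property
    def duration(self) -> float:
        """Pulse duration, one period of the pulse frequency (s)."""
        return 1.0 / self.frequency


def _pulse_values(t: np.ndarray, start: float, spec: PulseSpec) -> np.ndarray:
    """Raised cosine peak*(1 - cos(2*pi*f*(t-start)))/2 on [start, start+T]."""
    tau = t - start
    inside = (tau >= 0.0) & (tau <= spec.duration)
    out = np.zeros_like(t)
    out[inside] = spec.peak * (1.0 - np.cos(2.0 * np.pi * spec.frequency * tau[inside])) / 2.0
    return out


def make_pulse(spec: PulseSpec = PulseSpec()) -> ForceTrace:
    """Generate one padded raised-cosine pulse as a :class:`ForceTrace`.

    The pulse occupies ``[pre_silence, pre_silence + 1/frequency]`` on the
    trace's time axis; everything else is zero.  The sampled maximum is
    ``peak`` up to discretization (the analytic peak sits at mid-pulse, which
    need not fall on the sample grid).
    """
    total = spec.pre_silence + spec.duration + spec.post_silence
    n = int(round(total * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    return ForceTrace(spec.sample_rate, _pulse_values(t, spec.pre_silence, spec))


def make_lagged_pair(
    spec: PulseSpec, lag_ms: float
) -> tuple[ForceTrace, ForceTrace]:
    """Build the (vertical, horizontal) pulse pair for one lag condition.

    For ``lag_ms > 0`` the vertical pulse onset precedes the horizontal one
    by exactly ``lag_ms``; for negative lags the horizontal pulse leads.
    Both traces share the same time base and length.  The lag must be an
    integer number of samples at ``spec.sample_rate``.
    """
    lag_s = lag_ms / 1000.0
    if abs(lag_s) > spec.post_silence:
        raise ValueError(
            f"|lag| = {abs(lag_ms)} ms exceeds the post-silence padding "
            f"({spec.post_silence * 1000:.0f} ms)"
        )
    n_shift = lag_s * spec.sample_rate
    if abs(n_shift - round(n_shift)) > 1e-9:
        raise ValueError(
            f"lag {lag_ms} ms is not an integer number of samples at "
            f"{spec.sample_rate} Hz"
        )
    start_v = spec.pre_silence + max(0.0, -lag_s)
    start_h = spec.pre_silence + max(0.0, lag_s)
    total = spec.pre_silence + abs(lag_s) + spec.duration + spec.post_silence
    n = int(round(total * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    vertical = ForceTrace(spec.sample_rate, _pulse_values(t, start_v, spec))
    horizontal = ForceTrace(spec.sample_rate, _pulse_values(t, start_h, spec))
    return vertical, horizontal


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered (trial_id, lag_ms) pairs realizing the pseudo-random design."""

    entries: tuple[tuple[int, int], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def lags(self) -> tuple[int, ...]:
        return tuple(lag for _, lag in self.entries)


def schedule_trials(
    lags: Sequence[int] = DESIGN_LAGS_MS,
    reps: int = 15,
    seed: int = 0,
) -> TrialSchedule:
    """Seeded uniform permutation of the ``reps``-fold multiset of lags.

    Each lag appears exactly ``reps`` times; with the default 14 lags and 15
    repetitions the schedule has 210 trials.  Trial ids start at 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(lags) == 0:
        raise ValueError("lags must be non-empty")
    pool = np.repeat(np.asarray(lags, dtype=int), reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)
    entries = tuple((i + 1, int(lag)) for i, lag in enumerate(order))
    return TrialSchedule(entries=entries, seed=seed)
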