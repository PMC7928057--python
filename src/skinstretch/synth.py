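"""Synthetic data generation: Bernoulli responders for the TOJ task and
noisy device recording sets over the full trial design.

The responder is the generative twin of the analysis model: each response is
Bernoulli with P(vertical first) = lapse/2 + (1 - lapse) * logistic((lag -
mu)/s), s = jnd / ln 3.  The default parameters are the group values the
evaluation experiment reports (PSE -18.37 ms, JND 25.15 ms, 3 participants),
so recovery experiments are run under the study's own conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .device import DeviceConfig, TrialRecording, simulate_trial
from .stimulus import PulseSpec, TrialSchedule, make_lagged_pair
from .toj import LN3

__all__ = [
    "ResponderParams",
    "CohortSpec",
    "simulate_responder",
    "simulate_cohort",
    "simulate_recording_set",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ResponderParams:
    """Generative logistic responder: location mu (ms), jnd (ms), lapse."""

    mu: float = -18.37
    jnd: float = 25.15
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.jnd > 0):
            raise ValueError("jnd must be strictly positive")
        if not (0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")

    @property
    def s(self) -> float:
        """Implied logistic scale, ms."""
        return self.jnd / LN3


@dataclass(frozen=True)
class CohortSpec:
    """Population the cohort is drawn from.

    Per-participant (mu, jnd) are normal around the responder defaults with
    the given between-participant standard deviations (jnd truncated > 0).
    """

    n_participants: int = 3
    between_participant_sd_mu: float = 12.5
    between_participant_sd_jnd: float = 3.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.between_participant_sd_mu < 0 or self.between_participant_sd_jnd < 0:
            raise ValueError("between-participant sds must be non-negative")


def response_probability(params: ResponderParams, lag_ms) -> np.ndarray:
    """P('vertical first') at the given lag(s) under the responder model."""
    base = expit((np.asarray(lag_ms, dtype=float) - params.mu) / params.s)
    return params.lapse / 2.0 + (1.0 - params.lapse) * base


def simulate_responder(
    params: ResponderParams,
    schedule: TrialSchedule,
    participant_id: str = "P01",
) -> pd.DataFrame:
    """Draw one participant's binary responses over a trial schedule.

    Returns a response table with columns participant_id, trial_id, lag_ms,
    response (1 = 'vertical first').  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lags = np.asarray(schedule.lags, dtype=float)
    p = response_probability(params, lags)
    responses = (rng.random(lags.size) < p).astype(int)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_id": [tid for tid, _ in schedule.entries],
            "lag_ms": lags.astype(int),
            "response": responses,
        }
    )


def simulate_cohort(
    spec: CohortSpec,
    responder_defaults: ResponderParams = ResponderParams(),
    schedule: TrialSchedule | None = None,
) -> pd.DataFrame:
    """Simulate a multi-participant cohort as one stacked response table.

    Participant parameters are drawn from the cohort population; with both
    sds equal to zero every participant shares the defaults.  Reproducible
    given ``spec.seed``.
    """
    from .stimulus import schedule_trials

    if schedule is None:
        schedule = schedule_trials(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    tables = []
    for i in range(spec.n_participants):
        mu_i = rng.normal(responder_defaults.mu, spec.between_participant_sd_mu)
        jnd_i = rng.normal(responder_defaults.jnd, spec.between_participant_sd_jnd)
        while jnd_i <= 0:  # truncate the jnd distribution at zero
            jnd_i = rng.normal(responder_defaults.jnd, spec.between_participant_sd_jnd)
        seed_i = int(rng.integers(_SEED_MOD))
        params_i = ResponderParams(
            mu=float(mu_i), jnd=float(jnd_i), lapse=responder_defaults.lapse,
            seed=seed_i,
        )
        tables.append(
            simulate_responder(params_i, schedule, participant_id=f"P{i + 1:02d}")
        )
    return pd.concat(tables, ignore_index=True)


def simulate_recording_set(
    schedule: TrialSchedule,
    pulse_spec: PulseSpec = PulseSpec(),
    device: DeviceConfig = DeviceConfig(),
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """One simulated trial recording per schedule entry.

    Each trial draws independent sensing noise from a per-trial seed
    derived from the control config's base seed; the manifest maps
    trial_id -> (lag_ms, seed).  Deterministic given (schedule, config).
    """
    from dataclasses import replace

    recordings: list[TrialRecording] = []
    manifest_rows = []
    base = device.control.seed
    for trial_id, lag in schedule.entries:
        trial_seed = int((base + 7919 * trial_id) % _SEED_MOD)
        control = replace(device.control, seed=trial_seed)
        pair = make_lagged_pair(pulse_spec, lag)
        rec = simulate_trial(
            pair,
            (device.motor_v, device.motor_h),
            device.load,
            control,
            commanded_lag_ms=lag,
        )
        recordings.append(rec)
        manifest_rows.append({"trial_id": trial_id, "lag_ms": lag, "seed": trial_seed})
    return recordings, pd.DataFrame(manifest_rows)
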