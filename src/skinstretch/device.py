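"""Force-control loop simulation for the two-motor skin-stretch device.

Each channel commands a DC motor by current: the target force is converted to
a target current through the inverse motor model (force = force_constant x
current), the sensed current is compared to the target, and the error drives
a discrete PID controller whose output (plus the feedforward target current)
is applied to a first-order electrical plant.  The facial-skin load enters as
a disturbance current: the skin spring in series with the wire/tab coupling
absorbs the fraction beta = stiffness / (stiffness + coupling_stiffness) of
the produced current-equivalent force, so measured current is attenuated
relative to target when the skin is attached, and unaffected when unloaded —
matching how the physical device behaves when gains are tuned unloaded.

The loop runs at the control rate (100 Hz by default), so stimulus timing is
quantized to 10 ms steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import ForceTrace

__all__ = [
    "MotorParams",
    "SkinLoad",
    "ControlConfig",
    "PIDState",
    "TrialRecording",
    "DeviceConfig",
    "inverse_motor_model",
    "forward_force",
    "pid_step",
    "simulate_trial",
    "spatial_trajectory",
]


@dataclass(frozen=True)
class MotorParams:
    """Lumped electrical/electromagnetic constants of one actuator.

    ``force_constant`` (N/A) is the torque constant divided by the pulley
    radius; ``max_current`` (A) bounds every commanded current.
    """

    force_constant: float = 1.0
    terminal_resistance: float = 2.1
    electrical_time_constant: float = 1e-3
    max_current: float = 4.0

    def __post_init__(self) -> None:
        for name in ("force_constant", "terminal_resistance",
                     "electrical_time_constant", "max_current"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SkinLoad:
    """Quasi-static spring–damper load seen by one motor.

    ``stiffness`` (N/m) is the facial-skin stiffness at the stimulation
    site; ``coupling_stiffness`` (N/m) is the series stiffness of the wire
    and tab that transmit the pull.  ``stiffness = damping = 0`` encodes the
    unloaded bench condition (motor disconnected from the skin).
    ``moving_mass`` (kg) is the effective mass of the moving tissue+tab; the
    quasi-static plant neglects its inertia but the field is validated and
    kept for forward compatibility.
    """

    stiffness: float = 0.0
    damping: float = 0.0
    moving_mass: float = 0.01
    coupling_stiffness: float = 500.0

    def __post_init__(self) -> None:
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("stiffness and damping must be non-negative")
        if not (self.moving_mass > 0):
            raise ValueError("moving_mass must be strictly positive")
        if not (self.coupling_stiffness > 0):
            raise ValueError("coupling_stiffness must be strictly positive")

    @property
    def reaction_fraction(self) -> float:
        """Fraction of produced current absorbed by the skin spring."""
        return self.stiffness / (self.stiffness + self.coupling_stiffness)


@dataclass(frozen=True)
class ControlConfig:
    """PID gains and loop parameters for the current controller.

    Gains are dimensionless drive per ampere of current error.  ``noise_sd``
    (A) is the standard deviation of additive Gaussian current-sensing
    noise; the default is calibrated so that per-trial onset-lag jitter has
    a standard deviation of about 1.5 ms under the default device
    configuration.  ``feedforward`` selects whether the target current is
    applied directly in addition to the PID correction (as in the device's
    block diagram) or only the PID path drives the motor.
    """

    kp: float = 0.5
    ki: float = 2.0
    kd: float = 0.0
    sample_rate: float = 100.0
    noise_sd: float = 0.03
    seed: int = 0
    feedforward: bool = True

    def __post_init__(self) -> None:
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be positive")
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class PIDState:
    """Controller memory: accumulated integral and previous error."""

    integral: float = 0.0
    prev_error: float | None = None


@dataclass(frozen=True)
class TrialRecording:
    """Paired target and measured traces for one trial.

    ``commanded_lag`` is in ms, signed, positive = vertical leads.  Measured
    traces are the sensed motor current mapped to force through the motor's
    force constant.
    """

    commanded_lag: float
    target_v: ForceTrace
    target_h: ForceTrace
    measured_v: ForceTrace
    measured_h: ForceTrace

    def __post_init__(self) -> None:
        traces = (self.target_v, self.target_h, self.measured_v, self.measured_h)
        rates = {tr.sample_rate for tr in traces}
        lengths = {len(tr) for tr in traces}
        if len(rates) != 1:
            raise ValueError("all four traces must share one sample rate")
        if len(lengths) != 1:
            raise ValueError("all four traces must share one length")


@dataclass(frozen=True)
class DeviceConfig:
    """Bundle of per-channel motors, shared load and control settings."""

    motor_v: MotorParams = MotorParams()
    motor_h: MotorParams = MotorParams()
    load: SkinLoad = SkinLoad()
    control: ControlConfig = ControlConfig()


def inverse_motor_model(target_force: float, params: MotorParams) -> float:
    """Map a non-negative target force (N) to a commanded current (A).

    The wire-and-tab coupling can only pull, so negative forces are
    rejected.  The current is clipped to ``[0, max_current]``.
    """
    if not np.isfinite(target_force):
        raise ValueError("target_force must be finite")
    if target_force < 0:
        raise ValueError(
            f"target_force = {target_force} N < 0: the wire coupling can "
            "only pull the skin, pushing forces are not realizable"
        )
    return float(min(target_force / params.force_constant, params.max_current))


def forward_force(current: float, params: MotorParams) -> float:
    """Linear current (A) -> force (N) map; inverse of the motor model."""
    if not np.isfinite(current):
        raise ValueError("current must be finite")
    return float(params.force_constant * current)


def pid_step(
    error: float, state: PIDState, config: ControlConfig
) -> tuple[float, PIDState]:
    """One discrete PID update at the control rate.

    Backward-Euler integral (the current error is included in the
    accumulation), first-difference derivative on the error, no derivative
    filtering.  Returns the drive signal and the updated state.
    """
    if not math.isfinite(error):
        raise ValueError("PID error must be finite")
    dt = config.dt
    integral = state.integral + error * dt
    if state.prev_error is None:
        derivative = 0.0
    else:
        derivative = (error - state.prev_error) / dt
    drive = config.kp * error + config.ki * integral + config.kd * derivative
    return drive, PIDState(integral=integral, prev_error=error)


def _run_channel(
    target: ForceTrace,
    motor: MotorParams,
    load: SkinLoad,
    config: ControlConfig,
    rng: np.random.Generator,
) -> ForceTrace:
    """Step the closed loop for one channel; returns the measured-force trace."""
    dt = config.dt
    kf = motor.force_constant
    imax = motor.max_current
    # feedforward target current from the inverse motor model
    r = np.clip(target.values / kf, 0.0, imax)
    if np.any(target.values < 0):
        raise ValueError("target force trace contains negative samples")
    alpha = math.exp(-dt / motor.electrical_time_constant)
    beta = load.reaction_fraction
    damp_gain = load.damping / (load.stiffness + load.coupling_stiffness)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=len(r))
    else:
        noise = np.zeros(len(r))

    state = PIDState()
    i_now = 0.0
    i_prev = 0.0
    sensed = np.empty(len(r))
    for k in range(len(r)):
        y = i_now + noise[k]
        sensed[k] = y
        drive, state = pid_step(r[k] - y, state, config)
        if config.ki > 0:
            # anti-windup: the integral term alone may not exceed the
            # current limit
            bound = imax / config.ki
            clamped = float(np.clip(state.integral, -bound, bound))
            if clamped != state.integral:
                drive += config.ki * (clamped - state.integral)
                state = PIDState(integral=clamped, prev_error=state.prev_error)
        u = (r[k] if config.feedforward else 0.0) + drive
        u = float(np.clip(u, 0.0, imax))
        # skin reaction: spring fraction of the produced current plus a
        # damping term on its rate of change
        d = beta * i_now + damp_gain * (i_now - i_prev) / dt
        i_prev = i_now
        i_now = alpha * i_now + (1.0 - alpha) * (u - d)
        i_now = float(np.clip(i_now, 0.0, imax))
    return ForceTrace(config.sample_rate, kf * sensed, target.t0)


def simulate_trial(
    pulse_pair: tuple[ForceTrace, ForceTrace],
    motors: tuple[MotorParams, MotorParams],
    load: SkinLoad,
    config: ControlConfig,
    commanded_lag_ms: float = 0.0,
) -> TrialRecording:
    """Simulate one trial of the two-channel force-control loop.

    ``pulse_pair`` is the (vertical, horizontal) target pair; both traces
    must be sampled at the control rate and have equal length.  Gaussian
    sensing noise of sd ``config.noise_sd`` is drawn from ``config.seed``;
    the simulation is deterministic given (inputs, seed).
    """
    target_v, target_h = pulse_pair
    if target_v.sample_rate != config.sample_rate or target_h.sample_rate != config.sample_rate:
        raise ValueError("target traces must be sampled at the control rate")
    if len(target_v) != len(target_h):
        raise ValueError("target traces must have equal length")
    rng = np.random.default_rng(config.seed)
    measured_v = _run_channel(target_v, motors[0], load, config, rng)
    measured_h = _run_channel(target_h, motors[1], load, config, rng)
    return TrialRecording(
        commanded_lag=float(commanded_lag_ms),
        target_v=target_v,
        target_h=target_h,
        measured_v=measured_v,
        measured_h=measured_h,
    )


def spatial_trajectory(rec: TrialRecording, which: str = "target") -> np.ndarray:
    """Pointwise (horizontal, vertical) force pairs traced during a trial.

    For lag -> 0 the target trajectory lies on the diagonal; near a
    half-cycle lag it traces an L-shaped loop (one channel near zero while
    the other peaks).
    """
    if which == "target":
        h, v = rec.target_h, rec.target_v
    elif which == "measured":
        h, v = rec.measured_h, rec.measured_v
    else:
        raise ValueError("which must be 'target' or 'measured'")
    return np.column_stack([h.values, v.values])
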