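"""Recording-protocol state machine and session simulator.

The lander's recorder runs a four-step process: it boots (STARTING),
signals readiness (READY, status LED still), records rotating video
while WORKING, is paused to STANDBY with a magnet swipe on the reed
switch, and from STANDBY is either resumed (another swipe) or shut
down (SHUTDOWN), at which point the metadata CSV is flushed to disk.

While WORKING, the housing advances in exact angular steps (60 deg by
default, indexed mechanically by a Maltese cross) and dwells on each
fixed frame (30 s by default): six frames per full rotation, so one
rotation takes ~3 min and the standard three-rotation observation ~9
min.  Pressure and temperature are sampled on a fixed period into the
session log.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "RecorderState",
    "RecorderEvent",
    "ProtocolError",
    "ProtocolConfig",
    "SessionLog",
    "Recorder",
    "transition",
    "rotation_index",
    "run_observation",
    "write_session_csv",
    "constant_sensor",
    "ramp_sensor",
    "random_walk_sensor",
]


class RecorderState(str, Enum):
    STARTING = "STARTING"
    READY = "READY"
    WORKING = "WORKING"
    STANDBY = "STANDBY"
    SHUTDOWN = "SHUTDOWN"


class RecorderEvent(str, Enum):
    BOOT_COMPLETE = "boot_complete"
    MAGNET = "magnet"
    TIMER_TICK = "timer_tick"
    SHUTDOWN_MAGNET = "shutdown_magnet"


class ProtocolError(RuntimeError):
    """An event arrived in a state where it is not legal."""


#: Legal transitions of the recording process.  A magnet swipe starts
#: recording from READY, pauses WORKING to STANDBY, resumes STANDBY to
#: WORKING; the dedicated shutdown swipe is only honoured in STANDBY,
#: so no run can shut down without passing through standby first.
_TRANSITIONS: dict[tuple[RecorderState, RecorderEvent], RecorderState] = {
    (RecorderState.STARTING, RecorderEvent.BOOT_COMPLETE): RecorderState.READY,
    (RecorderState.READY, RecorderEvent.MAGNET): RecorderState.WORKING,
    (RecorderState.WORKING, RecorderEvent.TIMER_TICK): RecorderState.WORKING,
    (RecorderState.WORKING, RecorderEvent.MAGNET): RecorderState.STANDBY,
    (RecorderState.STANDBY, RecorderEvent.MAGNET): RecorderState.WORKING,
    (RecorderState.STANDBY, RecorderEvent.SHUTDOWN_MAGNET): RecorderState.SHUTDOWN,
}


def transition(state: RecorderState, event: RecorderEvent) -> RecorderState:
    """Next state for a (state, event) pair, or ProtocolError if illegal."""
    state = RecorderState(state)
    event = RecorderEvent(event)
    try:
        return _TRANSITIONS[(state, event)]
    except KeyError:
        raise ProtocolError(f"event {event.value!r} is illegal in state "
                            f"{state.value}") from None


@dataclass(frozen=True)
class ProtocolConfig:
    """Rotation/recording protocol parameters.

    Defaults are the standard survey protocol: 60 deg steps every 30 s,
    six frames per rotation, three rotations per observation.
    """

    step_deg: float = 60.0
    dwell_s: float = 30.0
    frames_per_rotation: int = 6
    rotations_per_observation: int = 3
    sensor_sample_period_s: float = 10.0
    motor_align_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.step_deg <= 0 or self.dwell_s <= 0:
            raise ValueError("step_deg and dwell_s must be positive")
        if self.frames_per_rotation <= 0 or self.rotations_per_observation <= 0:
            raise ValueError("frame and rotation counts must be positive")
        if self.sensor_sample_period_s <= 0:
            raise ValueError("sensor_sample_period_s must be positive")
        if abs(self.step_deg * self.frames_per_rotation - 360.0) > 1e-9:
            raise ValueError("step_deg * frames_per_rotation must equal 360")

    @property
    def rotation_duration_s(self) -> float:
        return self.frames_per_rotation * self.dwell_s

    @property
    def observation_duration_s(self) -> float:
        return self.rotations_per_observation * self.rotation_duration_s


def rotation_index(step_count: int,
                   frames_per_rotation: int = 6,
                   step_deg: float = 60.0) -> tuple[int, float]:
    """(position within rotation, cumulative angle) after N steps.

    The mechanical indexing guarantees exact multiples of the step
    angle, so position is simply ``step_count mod frames_per_rotation``
    and the cumulative angle ``step_count * step_deg``.
    """
    if step_count < 0:
        raise ValueError("step_count must be non-negative")
    return step_count % frames_per_rotation, step_count * step_deg


@dataclass
class SessionLog:
    """Ordered record of a simulated recording session."""

    events: list[tuple[float, str, str, float]] = field(default_factory=list)
    metadata_rows: list[tuple[str, float, float]] = field(default_factory=list)
    video_segments: list[tuple[float, float]] = field(default_factory=list)
    config: ProtocolConfig | None = None

    def validate(self) -> None:
        times = [t for t, *_ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if self.config is not None:
            step = self.config.step_deg
            for _, _, _, angle in self.events:
                if abs(angle / step - round(angle / step)) > 1e-9:
                    raise ValueError("cumulative angle not a multiple of step_deg")

    @property
    def total_video_s(self) -> float:
        return sum(b - a for a, b in self.video_segments)


SensorSource = Callable[[float], tuple[float, float]]


def constant_sensor(pressure_dbar: float = 10.0,
                    temperature_c: float = 18.0) -> SensorSource:
    """A fixed-reading pressure/temperature source."""
    return lambda t: (pressure_dbar, temperature_c)


def ramp_sensor(p0: float = 10.0, dp_dt: float = 0.0,
                t0: float = 18.0, dt_dt: float = 0.0) -> SensorSource:
    """Linear drift in pressure and temperature."""
    return lambda t: (p0 + dp_dt * t, t0 + dt_dt * t)


def random_walk_sensor(seed: int, p0: float = 10.0, t0: float = 18.0,
                       sigma_p: float = 0.02, sigma_t: float = 0.01) -> SensorSource:
    """Seeded random-walk source (deterministic in call order)."""
    rng = np.random.default_rng(seed)
    state = {"p": p0, "t": t0}

    def source(t: float) -> tuple[float, float]:
        state["p"] += rng.normal(0.0, sigma_p)
        state["t"] += rng.normal(0.0, sigma_t)
        return state["p"], state["t"]

    return source


class Recorder:
    """Event-driven recorder simulation.

    Feed events with :meth:`handle`; time is advanced explicitly with
    :meth:`advance`.  The WORKING phase accumulates rotation steps on
    timer ticks and records one contiguous video segment per WORKING
    stretch.
    """

    def __init__(self, config: ProtocolConfig | None = None,
                 sensor_source: SensorSource | None = None,
                 start_time: _dt.datetime | None = None):
        self.config = config or ProtocolConfig()
        self.sensor_source = sensor_source or constant_sensor()
        self.start_time = start_time or _dt.datetime(2021, 9, 1, 9, 0, 0)
        self.state = RecorderState.STARTING
        self.time_s = 0.0
        self.step_count = 0
        self.log = SessionLog(config=self.config)
        self._segment_start: float | None = None
        self._next_sample_s = 0.0
        self._log_event("power_on")

    # -- internals ----------------------------------------------------
    def _log_event(self, event: str) -> None:
        _, angle = rotation_index(self.step_count,
                                  self.config.frames_per_rotation,
                                  self.config.step_deg)
        self.log.events.append((self.time_s, self.state.value, event, angle))

    def _sample_sensors(self) -> None:
        p, temp = self.sensor_source(self.time_s)
        ts = (self.start_time + _dt.timedelta(seconds=self.time_s)).isoformat()
        self.log.metadata_rows.append((ts, float(p), float(temp)))
        self._next_sample_s += self.config.sensor_sample_period_s

    # -- public API ---------------------------------------------------
    def advance(self, duration_s: float) -> None:
        """Advance simulated time, sampling sensors on schedule."""
        end = self.time_s + duration_s
        while self._next_sample_s <= end + 1e-9:
            self.time_s = self._next_sample_s
            self._sample_sensors()
        self.time_s = end

    def handle(self, event: RecorderEvent) -> RecorderState:
        event = RecorderEvent(event)
        new_state = transition(self.state, event)
        if event == RecorderEvent.TIMER_TICK:
            self.step_count += 1
        if (self.state, new_state) == (RecorderState.READY, RecorderState.WORKING) \
                or (self.state, new_state) == (RecorderState.STANDBY,
                                               RecorderState.WORKING):
            self.advance(self.config.motor_align_delay_s)
            self._segment_start = self.time_s
        if new_state in (RecorderState.STANDBY, RecorderState.SHUTDOWN) \
                and self._segment_start is not None:
            self.log.video_segments.append((self._segment_start, self.time_s))
            self._segment_start = None
        self.state = new_state
        self._log_event(event.value)
        return self.state

    def run_working_phase(self, n_rotations: int) -> None:
        """Execute n complete rotations of dwell-then-step cycles."""
        if self.state != RecorderState.WORKING:
            raise ProtocolError("run_working_phase requires the WORKING state")
        n_steps = n_rotations * self.config.frames_per_rotation
        for _ in range(n_steps):
            self.advance(self.config.dwell_s)
            self.handle(RecorderEvent.TIMER_TICK)


def run_observation(config: ProtocolConfig | None = None,
                    n_rotations: int | None = None,
                    sensor_source: SensorSource | None = None,
                    start_time: _dt.datetime | None = None) -> SessionLog:
    """Simulate one full deployment: boot, record, standby, shutdown.

    The WORKING phase runs ``n_rotations`` complete rotations (default:
    the protocol's rotations_per_observation), so the recorded video
    duration is exactly ``n_rotations * frames_per_rotation * dwell_s``
    seconds.
    """
    config = config or ProtocolConfig()
    if n_rotations is None:
        n_rotations = config.rotations_per_observation
    if n_rotations < 0:
        raise ValueError("n_rotations must be non-negative")
    rec = Recorder(config=config, sensor_source=sensor_source,
                   start_time=start_time)
    rec.handle(RecorderEvent.BOOT_COMPLETE)
    rec.handle(RecorderEvent.MAGNET)           # READY -> WORKING
    rec.run_working_phase(n_rotations)
    rec.handle(RecorderEvent.MAGNET)           # WORKING -> STANDBY
    rec.handle(RecorderEvent.SHUTDOWN_MAGNET)  # STANDBY -> SHUTDOWN
    rec.log.validate()
    if n_rotations == 0:
        rec.log.video_segments = [s for s in rec.log.video_segments
                                  if s[1] > s[0]]
    return rec.log


def write_session_csv(log: SessionLog, path) -> Path:
    """Write the session metadata to CSV.

    Header ``timestamp_iso,pressure_dbar,temperature_C``; one row per
    sensor sample.  Mirrors the on-instrument behaviour of flushing all
    metadata to a CSV file at shutdown.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp_iso", "pressure_dbar", "temperature_C"])
        for ts, p, temp in log.metadata_rows:
            writer.writerow([ts, f"{p:.3f}", f"{temp:.3f}"])
    return path
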