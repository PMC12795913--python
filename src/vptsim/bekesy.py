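"""Continuous-tracking (von Bekesy) threshold procedure.

The stimulus is on for the whole condition.  Amplitude starts at a 0%
command and ramps up at the initial rate until the participant presses
to report "detected"; each press toggles the reported state and reverses
the ramp direction.  After the second reversal the change rate drops to
the fine rate.  The condition completes once at least ``min_duration_s``
have elapsed and at least ``min_reversals`` reversals occurred; it is
abandoned as "ceiling" ("floor") if the amplitude dwells at the 100% (0%)
bound for ``bound_dwell_s`` with the last answer still "not detected"
("detected").

Time is discretized to the hardware tick (amplitude updates every
``tick_s``); press latencies round to the nearest tick, since sub-tick
dynamics are unobservable to the procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

from .errors import ConfigurationError, RunawayTrackError
from .observer import Observer
from .units import DeviceModel, StimulusLevel

COMPLETED = "completed"
CEILING = "ceiling"
FLOOR = "floor"


@dataclass(frozen=True)
class BekesyConfig:
    initial_rate_pct: float = 5.0
    fine_rate_pct: float = 2.0
    tick_s: float = 1.25
    min_duration_s: float = 30.0
    min_reversals: int = 8
    bound_dwell_s: float = 15.0
    max_duration_s: float = 600.0  # runaway guard, not a study rule

    def __post_init__(self) -> None:
        if min(self.initial_rate_pct, self.fine_rate_pct, self.tick_s,
               self.min_duration_s, self.bound_dwell_s, self.max_duration_s) <= 0:
            raise ConfigurationError("all BekesyConfig durations/rates must be positive")
        if self.min_reversals < 1:
            raise ConfigurationError("min_reversals must be >= 1")
        if self.fine_rate_pct > self.initial_rate_pct:
            raise ConfigurationError("fine rate must not exceed initial rate")


@dataclass(frozen=True)
class BekesyEvent:
    t_s: float
    percent: float
    level_db: Optional[float]
    reported_state: bool  # True = "detected" reported, after this epoch
    press_registered: bool
    reversal_index: Optional[int]


@dataclass(frozen=True)
class Reversal:
    t_s: float
    percent: float
    level_db: Optional[float]


@dataclass
class BekesyTrack:
    """Full event history of one continuous-tracking condition."""

    frequency_hz: float
    location: str
    events: List[BekesyEvent] = field(default_factory=list)
    reversals: List[Reversal] = field(default_factory=list)
    termination_reason: str = COMPLETED
    elapsed_s: float = 0.0
    method: str = "bekesy"

    @property
    def press_times(self) -> List[float]:
        return [e.t_s for e in self.events if e.press_registered]

    def to_jsonl(self) -> str:
        lines = []
        for e in self.events:
            lines.append(json.dumps({
                "t_s": e.t_s, "percent": e.percent, "level_db": e.level_db,
                "reported_state": "detected" if e.reported_state else "not_detected",
                "press": e.press_registered, "reversal": e.reversal_index,
            }))
        return "\n".join(lines) + "\n"


def run_bekesy(
    observer: Observer,
    frequency_hz: float,
    location: str,
    device: DeviceModel,
    config: BekesyConfig = BekesyConfig(),
) -> BekesyTrack:
    """Simulate one continuous-tracking condition.

    Per epoch: (1) move the command by the active rate in the current
    direction, clamped to [0, 100]; (2) the observer samples a detection
    at the new level (guess rate at stimulus-off); (3) if no press is
    pending and the sampled state differs from the reported state, a
    press is scheduled at the sampled latency, rounded to the nearest
    epoch (a single toggle key cannot race itself, so at most one press
    is pending); (4) a due press toggles the reported state, flips the
    ramp direction, and records a reversal at the current level; (5) the
    three termination rules are evaluated.
    """
    observer.params(frequency_hz, location)  # fail fast if unconfigured
    track = BekesyTrack(frequency_hz=frequency_hz, location=location)

    percent = 0.0
    direction = 1.0
    reported = False  # initial "last answer" is "not detected" (no press yet)
    pending_epoch: Optional[int] = None
    rate = config.initial_rate_pct
    bound_start: Optional[float] = None  # time percent first continuously at a bound
    bound_value: Optional[float] = None

    k = 0
    while True:
        k += 1
        t = k * config.tick_s
        if t > config.max_duration_s:
            raise RunawayTrackError(
                f"bekesy track at {frequency_hz} Hz/{location} exceeded "
                f"{config.max_duration_s} s without terminating"
            )
        percent = min(100.0, max(0.0, percent + direction * rate))
        level: StimulusLevel = device.level(percent, frequency_hz)

        sampled = observer.detect(frequency_hz, location, level)
        if pending_epoch is None and sampled != reported:
            latency = observer.sample_latency(detected=sampled)
            pending_epoch = k + round(latency / config.tick_s)

        press = False
        reversal_index: Optional[int] = None
        if pending_epoch is not None and k >= pending_epoch:
            press = True
            pending_epoch = None
            reported = not reported
            direction = -direction
            track.reversals.append(Reversal(t_s=t, percent=percent, level_db=level.db))
            reversal_index = len(track.reversals)
            if len(track.reversals) >= 2:
                rate = config.fine_rate_pct

        track.events.append(BekesyEvent(
            t_s=t, percent=percent, level_db=level.db,
            reported_state=reported, press_registered=press,
            reversal_index=reversal_index,
        ))

        # bound dwell bookkeeping (after this epoch's move)
        if percent in (0.0, 100.0):
            if bound_value != percent:
                bound_value = percent
                bound_start = t
        else:
            bound_value = None
            bound_start = None

        track.elapsed_s = t
        if t >= config.min_duration_s and len(track.reversals) >= config.min_reversals:
            track.termination_reason = COMPLETED
            return track
        if bound_start is not None and t - bound_start >= config.bound_dwell_s:
            if bound_value == 100.0 and not reported:
                track.termination_reason = CEILING
                return track
            if bound_value == 0.0 and reported:
                track.termination_reason = FLOOR
                return track
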