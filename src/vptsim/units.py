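"""Acceleration unit conversions and the stimulus-device model.

Vibration amplitudes are expressed three ways: as the command sent to the
actuator (a percentage of full power), as rms acceleration in g, and as a
level in dB re 10^-6 m/s^2 rms (the ISO 13091-1 reference).  A command of
0% is "stimulus off" and has no dB value; it is represented by a sentinel
level, never by -inf arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ConfigurationError

#: Standard gravity in m/s^2 per g.
STANDARD_GRAVITY = 9.80665

#: ISO 13091-1 reference acceleration, m/s^2 rms.
REF_ACCEL_MS2 = 1e-6


@dataclass(frozen=True)
class UnitConstants:
    """Physical constants for the g <-> dB conversion.

    ``one_g`` is configurable (m/s^2 per g); ``ref_db`` is fixed at
    10^-6 m/s^2 by the ISO scale definition.
    """

    one_g: float = STANDARD_GRAVITY
    ref_db: float = REF_ACCEL_MS2

    def __post_init__(self) -> None:
        if not self.one_g > 0:
            raise ConfigurationError(f"one_g must be positive, got {self.one_g}")
        if self.ref_db != REF_ACCEL_MS2:
            raise ConfigurationError("ref_db is fixed at 1e-6 m/s^2")


DEFAULT_CONSTANTS = UnitConstants()


def accel_to_db(g: float, constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert rms acceleration in g to level in dB re 10^-6 m/s^2.

    dB = 20*log10(g*one_g / 1e-6).  Raises for non-positive g; the
    stimulus-off case must be handled upstream via the sentinel level.
    """
    if not g > 0:
        raise ValueError(f"acceleration must be positive, got {g}")
    amp = g * constants.one_g
    return 20.0 * math.log10(amp / constants.ref_db)


def db_to_accel(db: float, constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a level in dB re 10^-6 m/s^2 to rms acceleration in g."""
    if not math.isfinite(db):
        raise ValueError(f"db must be finite, got {db}")
    amp = constants.ref_db * 10.0 ** (db / 20.0)
    return amp / constants.one_g


@dataclass(frozen=True)
class StimulusLevel:
    """One stimulus intensity: command percent plus its physical values.

    ``db`` and ``g_rms`` are ``None`` exactly when ``percent == 0``
    (stimulus off).
    """

    percent: float
    db: Optional[float]
    g_rms: Optional[float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percent out of [0, 100]: {self.percent}")
        if (self.percent == 0.0) != (self.db is None):
            raise ValueError("db must be None iff percent == 0")

    @property
    def is_off(self) -> bool:
        return self.percent == 0.0


#: Sentinel for a 0% command.
STIMULUS_OFF = StimulusLevel(percent=0.0, db=None, g_rms=None)

LINEAR_ACCELERATION = "linear_acceleration"
LINEAR_DB = "linear_db"


@dataclass(frozen=True)
class DeviceModel:
    """Maps a percent-of-power command to a stimulus intensity per frequency.

    Two modes:

    * ``linear_acceleration`` — output acceleration scales linearly with
      the command, reaching a per-frequency ceiling (g rms) at 100%; this
      emulates a piezo actuator whose amplitude follows its drive.
    * ``linear_db`` — the command maps linearly onto the dB axis,
      db = db_min + (percent-1)/99 * (db_max-db_min), so every 1% step is
      the same decibel increment; up-down convergence theory assumes equal
      steps on the decision axis, and this mode realizes that exactly.
    """

    mode: str
    ceiling_g: Optional[Mapping[float, float]] = None
    db_min: Optional[float] = None
    db_max: Optional[float] = None
    constants: UnitConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if self.mode == LINEAR_ACCELERATION:
            if not self.ceiling_g:
                raise ConfigurationError("linear_acceleration mode needs ceiling_g")
            for f, c in self.ceiling_g.items():
                if not c > 0:
                    raise ConfigurationError(f"ceiling for {f} Hz must be > 0, got {c}")
        elif self.mode == LINEAR_DB:
            if self.db_min is None or self.db_max is None:
                raise ConfigurationError("linear_db mode needs db_min and db_max")
            if not self.db_max > self.db_min:
                raise ConfigurationError("db_max must exceed db_min")
        else:
            raise ConfigurationError(f"unknown device mode {self.mode!r}")

    @classmethod
    def linear_acceleration(
        cls, ceiling_g: Mapping[float, float], constants: UnitConstants = DEFAULT_CONSTANTS
    ) -> "DeviceModel":
        return cls(mode=LINEAR_ACCELERATION, ceiling_g=dict(ceiling_g), constants=constants)

    @classmethod
    def linear_db(
        cls, db_min: float, db_max: float, constants: UnitConstants = DEFAULT_CONSTANTS
    ) -> "DeviceModel":
        return cls(mode=LINEAR_DB, db_min=db_min, db_max=db_max, constants=constants)

    def level(self, percent: float, frequency_hz: float) -> StimulusLevel:
        return percent_to_level(percent, frequency_hz, self, self.constants)


def identity_db_device() -> DeviceModel:
    """linear_db device whose dB value equals the command percent (1..100).

    Convenient for hand-traceable tests: steps of 5% and 2% are exactly
    5 dB and 2 dB.
    """
    return DeviceModel.linear_db(db_min=1.0, db_max=100.0)


def percent_to_level(
    percent: float,
    frequency_hz: float,
    device: DeviceModel,
    constants: UnitConstants = DEFAULT_CONSTANTS,
) -> StimulusLevel:
    """Realize a percent command as a :class:`StimulusLevel` on a device."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent out of [0, 100]: {percent}")
    if percent == 0.0:
        return STIMULUS_OFF
    if device.mode == LINEAR_ACCELERATION:
        assert device.ceiling_g is not None
        if frequency_hz not in device.ceiling_g:
            raise ConfigurationError(
                f"frequency {frequency_hz} Hz not configured on device "
                f"(known: {sorted(device.ceiling_g)})"
            )
        g = (percent / 100.0) * device.ceiling_g[frequency_hz]
        return StimulusLevel(percent=percent, db=accel_to_db(g, constants), g_rms=g)
    assert device.db_min is not None and device.db_max is not None
    db = device.db_min + ((percent - 1.0) / 99.0) * (device.db_max - device.db_min)
    return StimulusLevel(percent=percent, db=db, g_rms=db_to_accel(db, constants))
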