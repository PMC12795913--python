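"""Synthetic participants for threshold-tracking simulations.

An :class:`Observer` answers yes/no detection questions through a
psychometric function

    Psi(x) = guess + (1 - guess - lapse) * F((x - mu) / sigma)

defined on the dB axis (standard for vibrotactile work), samples a
reaction latency for each key press, and carries its own isolated RNG
stream so tracks replay exactly from a seed.  A :class:`PopulationModel`
draws observers whose per-condition midpoints share a participant-level
offset u_i ~ N(0, tau^2), the mechanism behind "intercepts vary across
participants" in the downstream mixed models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.special import ndtr

from .errors import ConfigurationError
from .units import StimulusLevel

CUMULATIVE_GAUSSIAN = "cumulative_gaussian"
DETERMINISTIC_STEP = "deterministic_step"

Condition = Tuple[float, str]  # (frequency_hz, location)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of one condition's psychometric function.

    ``guess_rate`` doubles as the false-alarm probability at stimulus-off.
    ``deterministic_step`` is an idealized observer (detect iff x >= mu,
    guess and lapse forced to 0) that consumes no randomness, used for
    hand-traceable tests.
    """

    mu_db: float
    sigma_db: float = 4.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    form: str = CUMULATIVE_GAUSSIAN

    def __post_init__(self) -> None:
        if self.form not in (CUMULATIVE_GAUSSIAN, DETERMINISTIC_STEP):
            raise ConfigurationError(f"unknown psychometric form {self.form!r}")
        if self.form == CUMULATIVE_GAUSSIAN and not self.sigma_db > 0:
            raise ConfigurationError("sigma_db must be positive")
        if self.form == DETERMINISTIC_STEP and (self.guess_rate or self.lapse_rate):
            raise ConfigurationError("deterministic_step forces guess = lapse = 0")
        if not (0.0 <= self.guess_rate <= 1.0 and 0.0 <= self.lapse_rate <= 1.0):
            raise ConfigurationError("guess/lapse rates must lie in [0, 1]")
        if self.guess_rate + self.lapse_rate > 1.0:
            raise ConfigurationError("guess_rate + lapse_rate must not exceed 1")

    def prob_detect(self, db: Optional[float]) -> float:
        """Psi evaluated at level ``db``; ``None`` means stimulus-off."""
        if db is None:
            return self.guess_rate
        if self.form == DETERMINISTIC_STEP:
            return 1.0 if db >= self.mu_db else 0.0
        z = (db - self.mu_db) / self.sigma_db
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * float(ndtr(z))


@dataclass(frozen=True)
class LatencyModel:
    """Reaction-latency distribution for key presses.

    ``lognormal`` is parameterized by its target mean and SD in seconds
    (moment matching).  With ``detection_only`` set, latency applies only
    to "detected" presses; "not detected" presses are instantaneous —
    the mechanism by which slow reactions inflate continuous-tracking
    thresholds on the rising flank.
    """

    kind: str = "zero"
    mean_s: float = 0.4
    sd_s: float = 0.15
    detection_only: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "lognormal"):
            raise ConfigurationError(f"unknown latency kind {self.kind!r}")
        if self.kind == "lognormal" and not (self.mean_s > 0 and self.sd_s > 0):
            raise ConfigurationError("lognormal latency needs positive mean_s and sd_s")

    def sample(self, rng: np.random.Generator, detected: bool = True) -> float:
        if self.kind == "zero":
            return 0.0
        if self.detection_only and not detected:
            return 0.0
        # moment-matched lognormal: E = mean_s, SD = sd_s
        s2 = math.log1p((self.sd_s / self.mean_s) ** 2)
        mu = math.log(self.mean_s) - s2 / 2.0
        return float(rng.lognormal(mean=mu, sigma=math.sqrt(s2)))


ZERO_LATENCY = LatencyModel(kind="zero")


class Observer:
    """A simulated participant: psychometric map, latency model, RNG stream."""

    def __init__(
        self,
        psych: Mapping[Condition, PsychometricParams],
        latency: LatencyModel = ZERO_LATENCY,
        seed: Union[int, np.random.SeedSequence, None] = 0,
        participant_id: Optional[str] = None,
        gender: Optional[str] = None,
    ) -> None:
        if not psych:
            raise ConfigurationError("observer needs at least one condition")
        self.psych: Dict[Condition, PsychometricParams] = dict(psych)
        self.latency = latency
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.participant_id = participant_id
        self.gender = gender

    def params(self, frequency_hz: float, location: str) -> PsychometricParams:
        key = (frequency_hz, location)
        if key not in self.psych:
            raise ConfigurationError(
                f"observer has no psychometric parameters for {key}; "
                f"configured conditions: {sorted(self.psych)}"
            )
        return self.psych[key]

    def detect(
        self, frequency_hz: float, location: str, level: Optional[StimulusLevel]
    ) -> bool:
        """Sample one yes/no detection at ``level`` (off or None = no stimulus)."""
        p = self.params(frequency_hz, location)
        db = None if level is None or level.is_off else level.db
        if p.form == DETERMINISTIC_STEP:
            # no RNG consumption: downstream tracks are exactly reproducible
            return p.prob_detect(db) >= 1.0
        prob = p.prob_detect(db)
        if prob <= 0.0:
            return False
        if prob >= 1.0:
            return True
        return bool(self.rng.random() < prob)

    def sample_latency(self, detected: bool = True) -> float:
        return self.latency.sample(self.rng, detected=detected)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "gender": self.gender,
            "latency": vars(self.latency).copy(),
            "psych": {
                f"{f}:{loc}": vars(p).copy() for (f, loc), p in sorted(self.psych.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass(frozen=True)
class PopulationModel:
    """Generator of observers with between-participant threshold spread.

    ``condition_means`` give the population-mean 50% point per
    (frequency, location); each drawn participant adds a shared offset
    u_i ~ N(0, tau_between^2) plus ``gender_effect`` for participants
    whose gender matches ``gender_effect_level``.
    """

    condition_means: Mapping[Condition, float]
    tau_between: float = 10.0
    sigma_psych: float = 4.0
    guess_rate: float = 0.02
    lapse_rate: float = 0.01
    form: str = CUMULATIVE_GAUSSIAN
    latency: LatencyModel = field(default=LatencyModel(kind="lognormal", mean_s=0.4, sd_s=0.15))
    gender_effect: float = 0.0
    gender_effect_level: str = "female"

    def __post_init__(self) -> None:
        if self.tau_between < 0:
            raise ConfigurationError("tau_between must be >= 0")
        if not self.condition_means:
            raise ConfigurationError("condition_means must not be empty")


def draw_participant(
    population: PopulationModel,
    participant_id: str,
    gender: str,
    seed: Union[int, np.random.SeedSequence],
) -> Observer:
    """Draw one observer from the population, reproducibly from ``seed``.

    The participant offset u_i is drawn from a dedicated child stream so
    the observer's in-track RNG stream is unaffected by how many
    population-level draws were made.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    draw_ss, track_ss = ss.spawn(2)
    u_i = 0.0
    if population.tau_between > 0:
        u_i = float(np.random.default_rng(draw_ss).normal(0.0, population.tau_between))
    shift = population.gender_effect if gender == population.gender_effect_level else 0.0
    psych = {
        cond: PsychometricParams(
            mu_db=mean + u_i + shift,
            sigma_db=population.sigma_psych,
            guess_rate=population.guess_rate if population.form == CUMULATIVE_GAUSSIAN else 0.0,
            lapse_rate=population.lapse_rate if population.form == CUMULATIVE_GAUSSIAN else 0.0,
            form=population.form,
        )
        for cond, mean in population.condition_means.items()
    }
    return Observer(
        psych=psych,
        latency=population.latency,
        seed=track_ss,
        participant_id=participant_id,
        gender=gender,
    )


def single_condition_observer(
    mu_db: float,
    sigma_db: float = 4.0,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    form: str = CUMULATIVE_GAUSSIAN,
    frequency_hz: float = 250.0,
    location: str = "index",
    latency: LatencyModel = ZERO_LATENCY,
    seed: Union[int, np.random.SeedSequence, None] = 0,
) -> Observer:
    """Convenience constructor for one-condition observers in tests/benchmarks."""
    params = PsychometricParams(
        mu_db=mu_db, sigma_db=sigma_db, guess_rate=guess_rate,
        lapse_rate=lapse_rate, form=form,
    )
    return Observer({(frequency_hz, location): params}, latency=latency, seed=seed)
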