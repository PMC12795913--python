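"""Trial-based transformed up-down (staircase) threshold procedure.

Each trial presents the stimulus for ``stim_s``, an LED prompts the
answer ``led_delay_s`` later, and the next trial starts ``inter_trial_s``
after the answer.  Under the paper-style 3-Down/1-Up rule the amplitude
decreases after ``n_down`` consecutive "detected" answers and increases
after ``n_up`` consecutive "not detected" answers, converging on the
level where P(n_down consecutive detections) = 1/2, i.e. the
(1/2)^(1/n_down) detection point — 79.4% for 3D/1U, 50% for 1D/1U.

Steps are the initial size until the second reversal is recorded and the
fine size thereafter.  The condition completes at ``max_reversals``
reversals; it is abandoned as ceiling (floor) after ``bound_rule_count``
consecutive "not detected" ("detected") answers at the 100% (0%) bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

from .errors import ConfigurationError, RunawayTrackError
from .observer import Observer
from .units import DeviceModel

COMPLETED = "completed"
CEILING = "ceiling"
FLOOR = "floor"


@dataclass(frozen=True)
class StaircaseConfig:
    n_down: int = 3
    n_up: int = 1
    initial_step_pct: float = 5.0
    fine_step_pct: float = 2.0
    stim_s: float = 2.0
    led_delay_s: float = 1.0
    inter_trial_s: float = 1.0
    max_reversals: int = 8
    bound_rule_count: int = 3
    max_trials: int = 10_000  # runaway guard

    def __post_init__(self) -> None:
        if min(self.n_down, self.n_up, self.max_reversals, self.bound_rule_count) < 1:
            raise ConfigurationError("counts in StaircaseConfig must be >= 1")
        if min(self.initial_step_pct, self.fine_step_pct, self.stim_s,
               self.led_delay_s, self.inter_trial_s) <= 0:
            raise ConfigurationError("steps and durations must be positive")


@dataclass(frozen=True)
class Trial:
    index: int
    percent: float
    level_db: Optional[float]
    detected: bool
    t_answer_s: float
    reversal_index: Optional[int] = None


@dataclass(frozen=True)
class StaircaseReversal:
    trial_index: int
    percent: float
    level_db: Optional[float]


@dataclass
class StaircaseTrack:
    """Full trial history of one staircase condition."""

    frequency_hz: float
    location: str
    trials: List[Trial] = field(default_factory=list)
    reversals: List[StaircaseReversal] = field(default_factory=list)
    termination_reason: str = COMPLETED
    method: str = "staircase"

    def to_jsonl(self) -> str:
        lines = []
        for tr in self.trials:
            lines.append(json.dumps({
                "trial": tr.index, "percent": tr.percent, "level_db": tr.level_db,
                "response": "detected" if tr.detected else "not_detected",
                "t_answer_s": tr.t_answer_s, "reversal": tr.reversal_index,
            }))
        return "\n".join(lines) + "\n"


def run_staircase(
    observer: Observer,
    frequency_hz: float,
    location: str,
    device: DeviceModel,
    config: StaircaseConfig = StaircaseConfig(),
) -> StaircaseTrack:
    """Simulate one staircase condition.

    Trial 1 is at 0% (stimulus off, so the answer is a guess-rate draw).
    Consecutive-answer counters reset whenever the amplitude changes; a
    reversal is recorded, at the level of the trial whose answer
    completed the rule, whenever the applied change direction opposes the
    previous one.  The step size becomes the fine step for every change
    after the second reversal has been recorded.
    """
    observer.params(frequency_hz, location)
    track = StaircaseTrack(frequency_hz=frequency_hz, location=location)

    percent = 0.0
    prev_direction = 1.0  # trajectory starts "up"
    det_run = 0       # consecutive "detected" since last change
    nondet_run = 0    # consecutive "not detected" since last change
    ceil_run = 0      # consecutive "not detected" answered at 100%
    floor_run = 0     # consecutive "detected" answered at 0%
    t = 0.0

    for index in range(1, config.max_trials + 1):
        level = device.level(percent, frequency_hz)
        detected = observer.detect(frequency_hz, location, level)
        latency = observer.sample_latency(detected=detected)
        if index == 1:
            t = config.stim_s + config.led_delay_s + latency
        else:
            t = t + config.inter_trial_s + config.stim_s + config.led_delay_s + latency

        ceil_run = ceil_run + 1 if (percent >= 100.0 and not detected) else 0
        floor_run = floor_run + 1 if (percent <= 0.0 and detected) else 0
        if ceil_run >= config.bound_rule_count or floor_run >= config.bound_rule_count:
            # bound abandonment pre-empts any reversal this answer would imply
            track.trials.append(Trial(index=index, percent=percent, level_db=level.db,
                                      detected=detected, t_answer_s=t))
            track.termination_reason = (CEILING if ceil_run >= config.bound_rule_count
                                        else FLOOR)
            return track

        change = 0.0
        if detected:
            nondet_run = 0
            det_run += 1
            if det_run >= config.n_down:
                change = -1.0
        else:
            det_run = 0
            nondet_run += 1
            if nondet_run >= config.n_up:
                change = 1.0

        reversal_index: Optional[int] = None
        if change != 0.0 and change != prev_direction:
            track.reversals.append(
                StaircaseReversal(trial_index=index, percent=percent, level_db=level.db)
            )
            reversal_index = len(track.reversals)

        track.trials.append(Trial(
            index=index, percent=percent, level_db=level.db,
            detected=detected, t_answer_s=t, reversal_index=reversal_index,
        ))

        if len(track.reversals) >= config.max_reversals:
            track.termination_reason = COMPLETED
            return track

        if change != 0.0:
            prev_direction = change
            det_run = 0
            nondet_run = 0
            step = (config.fine_step_pct if len(track.reversals) >= 2
                    else config.initial_step_pct)
            percent = min(100.0, max(0.0, percent + change * step))

    raise RunawayTrackError(
        f"staircase at {frequency_hz} Hz/{location} exceeded "
        f"{config.max_trials} trials without terminating"
    )
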