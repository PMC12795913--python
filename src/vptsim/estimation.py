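"""Reversal-based threshold estimators and time-to-complete.

Both procedures estimate the threshold from reversal levels on the dB
scale, discarding the first two reversals (the coarse-step approach).
A condition that did not reach the required reversal count yields a
missing estimate (``None``), mirroring the NA exclusions applied before
the statistical stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

from .bekesy import COMPLETED, BekesyTrack
from .observer import Observer
from .staircase import StaircaseTrack


@dataclass(frozen=True)
class ThresholdEstimate:
    """A VPT in dB re 10^-6 m/s^2 (or missing) with its bookkeeping."""

    vpt_db: Optional[float]
    reversals_used: int
    method: str
    termination_reason: str
    ttc_s: Optional[float]


def _mean(levels: List[float]) -> float:
    return sum(levels) / len(levels)


def staircase_threshold(track: StaircaseTrack) -> ThresholdEstimate:
    """Average of reversal levels 3..8 for tracks with exactly 8 reversals.

    Tracks abandoned at a bound (fewer than 8 reversals) yield a missing
    estimate and missing time-to-complete.
    """
    n = len(track.reversals)
    if n != 8 or track.termination_reason != COMPLETED:
        return ThresholdEstimate(None, 0, "staircase", track.termination_reason, None)
    levels = [r.level_db for r in track.reversals[2:]]
    if any(v is None for v in levels):
        # a used reversal at stimulus-off has no dB value; treat as unusable
        return ThresholdEstimate(None, 0, "staircase", track.termination_reason, None)
    return ThresholdEstimate(
        vpt_db=_mean(levels),  # type: ignore[arg-type]
        reversals_used=len(levels),
        method="staircase",
        termination_reason=track.termination_reason,
        ttc_s=time_to_complete(track),
    )


def bekesy_threshold(track: BekesyTrack) -> ThresholdEstimate:
    """Average of reversal pairs 3..R, dropping an odd tail reversal.

    With R total reversals (R >= 8 required), reversals 3..R are paired
    consecutively; if the span has odd length its last reversal is
    excluded so only complete pairs enter the mean (e.g. R = 13 averages
    reversals 3..12).  Averaging all paired levels equals the even-span
    mean, so that is what is computed.
    """
    n = len(track.reversals)
    if n < 8 or track.termination_reason != COMPLETED:
        return ThresholdEstimate(None, 0, "bekesy", track.termination_reason, None)
    levels = [r.level_db for r in track.reversals[2:]]
    if len(levels) % 2 == 1:
        levels = levels[:-1]
    if any(v is None for v in levels):
        return ThresholdEstimate(None, 0, "bekesy", track.termination_reason, None)
    return ThresholdEstimate(
        vpt_db=_mean(levels),  # type: ignore[arg-type]
        reversals_used=len(levels),
        method="bekesy",
        termination_reason=track.termination_reason,
        ttc_s=time_to_complete(track),
    )


def time_to_complete(track: Union[BekesyTrack, StaircaseTrack]) -> Optional[float]:
    """Interval between the first and last answers, when the track completed.

    Staircase: difference between the first and last trial answer times.
    Continuous tracking: difference between the first and last registered
    press times.  Missing when the threshold criterion is unmet.
    """
    if isinstance(track, StaircaseTrack):
        if track.termination_reason != COMPLETED or len(track.reversals) < 8:
            return None
        return track.trials[-1].t_answer_s - track.trials[0].t_answer_s
    if track.termination_reason != COMPLETED or len(track.reversals) < 8:
        return None
    presses = track.press_times
    if not presses:
        return None
    return presses[-1] - presses[0]


def estimate(track: Union[BekesyTrack, StaircaseTrack]) -> ThresholdEstimate:
    """Dispatch to the appropriate estimator by track type."""
    if isinstance(track, StaircaseTrack):
        return staircase_threshold(track)
    return bekesy_threshold(track)


def probability_at_estimate(
    observer: Observer, frequency_hz: float, location: str, vpt_db: float
) -> float:
    """Psi(vpt_db) under the observer's generating psychometric function."""
    return observer.params(frequency_hz, location).prob_detect(vpt_db)
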