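"""Turn detection from earth-frame vertical angular velocity.

During straight walking the vertical-axis angular velocity of a phone in
the pocket oscillates with small amplitude and frequent zero crossings.
During a turn it departs in one direction (sign depending on the phone's
orientation in the pocket) with no zero crossing, so the total angular
distance travelled in one direction is the integral of the angular
velocity between two consecutive zero crossings — the area under the
curve, AUC; a 180-degree turn integrates to pi radians. A segment is
flagged as a turn when AUC x segment duration exceeds a threshold
(default 2.00 radian-seconds). Strides overlapping a detected turn are
excluded from stride-time summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .gait_events import GaitEventSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurnInterval:
    """A detected turning period (half-open sample interval [start, end))."""

    start_index: int
    end_index: int
    auc: float          # radians, nonnegative
    duration: float     # seconds
    score: float        # radian-seconds, auc * duration

    def start_time(self, fs: float) -> float:
        return self.start_index / fs

    def end_time(self, fs: float) -> float:
        return self.end_index / fs


def segment_zero_crossings(wz_filt: np.ndarray) -> list[tuple[int, int]]:
    """Split a series into maximal runs of constant nonzero sign.

    Exact-zero samples terminate the current run and belong to no segment;
    the trial boundaries act as crossings. Returns half-open ``(start,
    end)`` index pairs in order.
    """
    s = np.sign(np.asarray(wz_filt, dtype=float))
    segments: list[tuple[int, int]] = []
    start = None
    cur = 0.0
    for i, si in enumerate(s):
        if si == 0:
            if start is not None:
                segments.append((start, i))
            start, cur = None, 0.0
        elif si != cur:
            if start is not None:
                segments.append((start, i))
            start, cur = i, si
    if start is not None:
        segments.append((start, len(s)))
    return segments


def _crossing_offset(x_outside: float, x_inside: float) -> float:
    """Distance (in samples) from the run-boundary sample to the zero
    crossing, by linear interpolation toward the outside sample."""
    return abs(x_inside) / (abs(x_inside) + abs(x_outside))


def score_segment(wz_filt: np.ndarray, segment: tuple[int, int], fs: float) -> TurnInterval:
    """Integrate one constant-sign segment into a scored turn candidate.

    The integration runs between the two zero crossings bounding the
    segment, located by linear interpolation between the boundary sample
    and its neighbour (trial edges act as crossings at the edge sample):
    trapezoids over the in-segment samples plus the two edge triangles.
    AUC is the absolute value of that integral — the direction of turning
    is deliberately discarded because it depends only on the phone's
    orientation in the pocket — and the duration is the crossing-to-
    crossing time.
    """
    wz_filt = np.asarray(wz_filt, dtype=float)
    start, end = segment
    dt = 1.0 / fs
    area = float(np.trapezoid(wz_filt[start:end], dx=dt))
    t0 = start * dt
    t1 = (end - 1) * dt
    if start > 0:
        off = _crossing_offset(wz_filt[start - 1], wz_filt[start])
        t0 -= off * dt
        area += 0.5 * wz_filt[start] * off * dt
    if end < len(wz_filt):
        off = _crossing_offset(wz_filt[end], wz_filt[end - 1])
        t1 += off * dt
        area += 0.5 * wz_filt[end - 1] * off * dt
    return TurnInterval(start_index=start, end_index=end, auc=abs(area),
                        duration=t1 - t0, score=abs(area) * (t1 - t0))


def detect_turns(wz_filt: np.ndarray, fs: float, threshold: float = 2.0) -> list[TurnInterval]:
    """All zero-crossing segments whose score exceeds ``threshold`` rad·s."""
    if threshold <= 0:
        raise ParameterError("turn threshold must be positive")
    turns = [score_segment(wz_filt, seg, fs)
             for seg in segment_zero_crossings(wz_filt)]
    return [t for t in turns if t.score > threshold]


def mask_strides(events: GaitEventSequence, turns: list[TurnInterval],
                 buffer_s: float = 0.0) -> GaitEventSequence:
    """Flag strides that overlap any detected turn (plus optional buffer).

    A stride spanning ``[hs_i, hs_{i+1}]`` is excluded iff that interval
    overlaps ``[turn_start - buffer, turn_end + buffer]`` for any turn.
    Modifies and returns ``events`` with its ``excluded`` flags set.
    """
    excluded = np.zeros(len(events.stride_times), dtype=bool)
    for turn in turns:
        t0 = turn.start_time(events.fs) - buffer_s
        t1 = turn.end_time(events.fs) + buffer_s
        overlap = (events.stride_start_times < t1) & (events.stride_end_times > t0)
        excluded |= overlap
    events.excluded = excluded
    logger.info("turn masking: %d of %d strides excluded",
                int(excluded.sum()), len(excluded))
    return events
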