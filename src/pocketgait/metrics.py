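"""Trial- and assessment-level gait summaries.

The unit of interest for all reliability analyses is the average stride
time of a trial (turn-overlapping strides excluded). The dual-task cost is
the percentage change in average stride time from a normal-walking trial
to its paired dual-task trial: even healthy adults slow their stride when
performing serial subtractions while walking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, PairingError
from .gait_events import GaitEventSequence
from .imu_io import Condition, TrialMeta


@dataclass
class TrialSummary:
    mean_stride_time: float
    sd_stride_time: float
    n_strides_included: int
    n_strides_excluded_turning: int
    meta: TrialMeta | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_stride_time_s": self.mean_stride_time,
            "sd_stride_time_s": self.sd_stride_time,
            "n_strides_included": self.n_strides_included,
            "n_strides_excluded_turning": self.n_strides_excluded_turning,
        }
        if self.meta is not None:
            d["condition"] = self.meta.condition.value
            d["setting"] = self.meta.setting.value
            d["participant_id"] = self.meta.participant_id
            d["visit_id"] = self.meta.visit_id
            d["trial_id"] = self.meta.trial_id
        return d


@dataclass
class DualTaskCost:
    """Percentage change in average stride time, normal -> dual task."""

    cost_percent: float
    normal: TrialSummary | None = None
    dual: TrialSummary | None = None


def summarize_trial(events: GaitEventSequence, meta: TrialMeta | None = None) -> TrialSummary:
    """Mean and SD of included stride times for one (turn-masked) trial.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 included strides: the trial is flagged, not silently
        dropped.
    """
    included = events.included_stride_times
    if len(included) < 2:
        raise InsufficientDataError(
            f"only {len(included)} included stride(s); need at least 2")
    return TrialSummary(
        mean_stride_time=float(np.mean(included)),
        sd_stride_time=float(np.std(included, ddof=1)),
        n_strides_included=len(included),
        n_strides_excluded_turning=events.n_strides_excluded,
        meta=meta if meta is not None else events.meta,
    )


def dual_task_cost(normal: TrialSummary, dual: TrialSummary) -> DualTaskCost:
    """Dual-task cost from a matched pair of trials.

    ``cost = 100 * (dual.mean - normal.mean) / normal.mean``; positive
    means dual tasking slowed the stride.

    Raises
    ------
    PairingError
        Trials are not from the same participant/assessment, or their
        conditions are not (normal, dual_task).
    """
    if normal.meta is not None and dual.meta is not None:
        if normal.meta.participant_id != dual.meta.participant_id:
            raise PairingError("trials are from different participants")
        if normal.meta.visit_id != dual.meta.visit_id:
            raise PairingError("trials are from different assessments")
        if (normal.meta.condition is not Condition.NORMAL
                or dual.meta.condition is not Condition.DUAL_TASK):
            raise PairingError("expected one normal and one dual_task trial")
    if normal.mean_stride_time <= 0:
        raise PairingError("normal-walking mean stride time must be positive")
    cost = 100.0 * (dual.mean_stride_time - normal.mean_stride_time) / normal.mean_stride_time
    return DualTaskCost(cost_percent=float(cost), normal=normal, dual=dual)


def assessment_mean(summaries: list[TrialSummary]) -> float:
    """Assessment-level average: unweighted mean of trial mean stride times."""
    if not summaries:
        raise InsufficientDataError("no trial summaries")
    return float(np.mean([s.mean_stride_time for s in summaries]))
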