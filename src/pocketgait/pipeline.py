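"""End-to-end trial analysis: rotate -> filter -> events -> turns -> summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gait_events import GaitEventSequence, extract_gait_events
from .imu_io import IMURecording, Setting, TrialMeta
from .metrics import TrialSummary, summarize_trial
from .preprocess import EarthFrameSeries, preprocess_recording
from .turns import TurnInterval, detect_turns, mask_strides


@dataclass
class TrialResult:
    """Everything the analysis of one trial produces."""

    series: EarthFrameSeries
    events: GaitEventSequence
    turns: list[TurnInterval]
    summary: TrialSummary

    def stride_table(self) -> pd.DataFrame:
        ev = self.events
        return pd.DataFrame({
            "stride_index": np.arange(len(ev.stride_times)),
            "hs_time_s": ev.stride_start_times,
            "stride_time_s": ev.stride_times,
            "excluded_for_turn": ev.excluded,
        })

    def turn_table(self) -> pd.DataFrame:
        fs = self.events.fs
        return pd.DataFrame({
            "start_s": [t.start_time(fs) for t in self.turns],
            "end_s": [t.end_time(fs) for t in self.turns],
            "auc_rad": [t.auc for t in self.turns],
            "duration_s": [t.duration for t in self.turns],
            "score": [t.score for t in self.turns],
        })


def analyze_trial(rec: IMURecording, meta: TrialMeta | None = None,
                  config: PipelineConfig | None = None,
                  detect_turns_always: bool | None = None) -> TrialResult:
    """Run the full pipeline on one recording.

    Turn detection and stride masking run for home-setting trials (or
    always, when ``detect_turns_always`` is true); lab trials on a straight
    walkway skip masking but still report any detected turns.
    """
    config = config or PipelineConfig()
    meta = meta or (rec.meta if rec.meta is not None else TrialMeta())
    series = preprocess_recording(rec, config)
    events = extract_gait_events(series.az_filt, series.fs, config, meta)
    turns = detect_turns(series.wz_filt, series.fs, config.turns_threshold_rad_s)
    apply_mask = detect_turns_always if detect_turns_always is not None \
        else meta.setting is Setting.HOME
    if apply_mask:
        events = mask_strides(events, turns, config.turns_buffer_s)
    summary = summarize_trial(events, meta)
    return TrialResult(series=series, events=events, turns=turns, summary=summary)
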