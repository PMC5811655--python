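"""Pipeline configuration.

Every constant that the analysis method leaves open (filter order and
cutoff, peak-picking parameters, turn threshold, stride plausibility
bounds, stride-matching window) lives here with its default, so a user can
see and override each one from a single YAML file or CLI flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their defaults.

    Attributes
    ----------
    filter_order : int
        Order of the low-pass Butterworth filter (applied forward-backward,
        so the effective magnitude response is squared).
    filter_cutoff_hz : float
        Low-pass cutoff in Hz for the vertical acceleration and, when
        ``turn_filter_wz`` is set, the vertical angular velocity. Gait
        fundamentals sit near 1-2 Hz; 5 Hz keeps informative harmonics.
    accel_unit : str
        Unit of accelerometer columns on disk: ``"m/s^2"`` or ``"g"``.
    events_prominence_frac : float
        Peak prominence threshold as a fraction of the SD of the filtered
        vertical acceleration.
    events_min_separation_s : float
        Minimum spacing between candidate peaks, seconds.
    stride_bounds_s : tuple[float, float]
        Physiologic plausibility bounds on a stride time, seconds. Values
        outside are dropped (and counted).
    turns_threshold_rad_s : float
        Turn score threshold in radian-seconds; a zero-crossing segment
        whose |AUC| x duration exceeds this is flagged as a turn.
    turns_filter_wz : bool
        Low-pass filter the vertical angular velocity (same filter as the
        acceleration channel) before zero-crossing segmentation.
    turns_buffer_s : float
        Extra margin added to each side of a detected turn when excluding
        overlapping strides.
    match_window_s : float
        Nearest-neighbour window for matching heel strikes between a test
        and a reference event stream, seconds.
    subtract_mean_accel : bool
        Subtract the per-trial mean from the vertical acceleration after
        filtering (the event logic is offset-invariant either way).
    """

    filter_order: int = 4
    filter_cutoff_hz: float = 5.0
    accel_unit: str = "m/s^2"
    events_prominence_frac: float = 0.3
    events_min_separation_s: float = 0.2
    stride_bounds_s: tuple[float, float] = (0.4, 2.5)
    turns_threshold_rad_s: float = 2.0
    turns_filter_wz: bool = True
    turns_buffer_s: float = 0.0
    match_window_s: float = 0.25
    subtract_mean_accel: bool = False

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if self.filter_cutoff_hz <= 0:
            raise ParameterError("filter_cutoff_hz must be positive")
        lo, hi = self.stride_bounds_s
        if not 0 < lo < hi:
            raise ParameterError("stride_bounds_s must satisfy 0 < low < high")
        if self.turns_threshold_rad_s <= 0:
            raise ParameterError("turns_threshold_rad_s must be positive")
        if self.accel_unit not in ("m/s^2", "g"):
            raise ParameterError("accel_unit must be 'm/s^2' or 'g'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stride_bounds_s"] = list(self.stride_bounds_s)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "stride_bounds_s" in d:
            d = dict(d)
            d["stride_bounds_s"] = tuple(d["stride_bounds_s"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
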