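"""Heel-strike / toe-off detection from filtered vertical acceleration.

With the phone in the front pocket, the filtered earth-frame vertical
acceleration of a walking trial shows two peaks per stride that alternate
between relatively high and relatively low amplitude. The trough nadir
(local minimum) following each high peak is the phone-side heel strike;
the trough nadir following each low peak is the phone-side toe-off. Stride
time is the elapsed time between two consecutive heel strikes of the same
(phone-side) foot, computed as the sample count between consecutive
heel-strike nadirs divided by the sampling frequency.

Only phone-side leg events are claimed; contralateral events are not
detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .errors import ClassificationError, InsufficientDataError
from .imu_io import TrialMeta

logger = logging.getLogger(__name__)


class EventKind(str, Enum):
    HEEL_STRIKE = "heel_strike"
    TOE_OFF = "toe_off"


@dataclass(frozen=True)
class GaitEvent:
    kind: EventKind
    index: int
    time: float


@dataclass
class PeakList:
    """Candidate peaks: sample indices, amplitudes and prominences."""

    indices: np.ndarray
    amplitudes: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class LabeledPeaks(PeakList):
    """Peaks with alternating high/low labels (True = high)."""

    is_high: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    violations: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_repaired: int = 0


@dataclass
class GaitEventSequence:
    """Ordered gait events of one trial plus derived stride times.

    ``stride_times[i]`` spans ``stride_start_times[i]`` to
    ``stride_end_times[i]`` (consecutive heel strikes). ``excluded`` flags
    strides masked out because they overlap a detected turn.
    """

    events: list[GaitEvent]
    fs: float
    stride_times: np.ndarray
    stride_start_times: np.ndarray
    stride_end_times: np.ndarray
    excluded: np.ndarray
    n_dropped_implausible: int = 0
    n_repaired_peaks: int = 0
    meta: TrialMeta | None = None

    @property
    def heel_strikes(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind is EventKind.HEEL_STRIKE]

    @property
    def toe_offs(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind is EventKind.TOE_OFF]

    @property
    def heel_strike_times(self) -> np.ndarray:
        return np.array([e.time for e in self.heel_strikes])

    @property
    def included_stride_times(self) -> np.ndarray:
        return self.stride_times[~self.excluded]

    @property
    def n_strides_included(self) -> int:
        return int(np.sum(~self.excluded))

    @property
    def n_strides_excluded(self) -> int:
        return int(np.sum(self.excluded))


def detect_peaks(az_filt: np.ndarray, fs: float,
                 prominence_frac: float = 0.3,
                 min_separation_s: float = 0.2) -> PeakList:
    """Find candidate peaks in the filtered vertical acceleration.

    Local maxima with prominence at least ``prominence_frac`` times the SD
    of the series and spacing at least ``min_separation_s`` apart.

    Raises
    ------
    InsufficientDataError
        Series shorter than 2 s or fewer than 4 peaks found.
    """
    az_filt = np.asarray(az_filt, dtype=float)
    if len(az_filt) < 2 * fs:
        raise InsufficientDataError("need at least 2 s of data for peak detection")
    sd = float(np.std(az_filt))
    if sd == 0:
        raise InsufficientDataError("constant signal: no peaks")
    indices, props = find_peaks(
        az_filt,
        prominence=prominence_frac * sd,
        distance=max(1, int(round(min_separation_s * fs))),
    )
    if len(indices) < 4:
        raise InsufficientDataError(f"only {len(indices)} peaks found; need at least 4")
    return PeakList(indices=indices, amplitudes=az_filt[indices],
                    prominences=props["prominences"])


def _parity_labels(amplitudes: np.ndarray) -> tuple[np.ndarray, float]:
    """Best alternating labelling: parity maximizing mean(high) - mean(low)."""
    n = len(amplitudes)
    even = np.arange(n) % 2 == 0
    sep_even = amplitudes[even].mean() - amplitudes[~even].mean()
    if sep_even >= 0:
        return even, float(sep_even)
    return ~even, float(-sep_even)


def _find_violations(amplitudes: np.ndarray, is_high: np.ndarray) -> np.ndarray:
    """Indices of high peaks smaller than both neighbouring low peaks."""
    bad = []
    for i in np.flatnonzero(is_high):
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < len(amplitudes)]
        if neigh and all(amplitudes[i] < amplitudes[j] for j in neigh):
            bad.append(i)
    return np.array(bad, dtype=int)


def classify_peaks(peaks: PeakList, max_repairs: int | None = None) -> LabeledPeaks:
    """Label peaks high/low by global parity optimization, with repair.

    The parity (odd vs even positions as "high") is the one maximizing
    ``mean(high amplitudes) - mean(low amplitudes)``. A high peak smaller
    than both of its neighbouring lows marks a spurious detection; the
    smallest-prominence peak in that neighbourhood is discarded and the
    classification re-run, up to ``max_repairs`` times (default: number of
    peaks). Remaining violations are flagged, not repaired.

    Raises
    ------
    ClassificationError
        Neither parity yields positive amplitude separation.
    InsufficientDataError
        Fewer than 4 peaks.
    """
    if len(peaks) < 4:
        raise InsufficientDataError("need at least 4 peaks to classify")
    if max_repairs is None:
        max_repairs = len(peaks)
    idx = peaks.indices.copy()
    amp = peaks.amplitudes.copy()
    prom = peaks.prominences.copy()
    n_repaired = 0
    while True:
        is_high, sep = _parity_labels(amp)
        if sep <= 0:
            raise ClassificationError(
                "no parity separates high from low peaks; trial rejected")
        violations = _find_violations(amp, is_high)
        if len(violations) == 0 or n_repaired >= max_repairs or len(idx) <= 4:
            break
        # Drop the least prominent peak around the first violation and retry.
        v = violations[0]
        neigh = [j for j in (v - 1, v, v + 1) if 0 <= j < len(idx)]
        drop = min(neigh, key=lambda j: prom[j])
        idx = np.delete(idx, drop)
        amp = np.delete(amp, drop)
        prom = np.delete(prom, drop)
        n_repaired += 1
    if n_repaired:
        logger.info("peak alternation repair discarded %d peak(s)", n_repaired)
    if len(violations):
        logger.warning("%d unresolved high/low alternation violations", len(violations))
    return LabeledPeaks(indices=idx, amplitudes=amp, prominences=prom,
                        is_high=is_high, violations=violations, n_repaired=n_repaired)


def locate_events(az_filt: np.ndarray, labeled: LabeledPeaks, fs: float) -> list[GaitEvent]:
    """Place events at the trough nadir trailing each peak.

    For each peak, the event sample is the minimum of ``az_filt`` between
    that peak and the next; a high peak yields a heel strike, a low peak a
    toe-off. The final peak, having no trailing inter-peak segment,
    produces no event.
    """
    az_filt = np.asarray(az_filt, dtype=float)
    events: list[GaitEvent] = []
    for i in range(len(labeled) - 1):
        a, b = labeled.indices[i], labeled.indices[i + 1]
        nadir = a + int(np.argmin(az_filt[a:b + 1]))
        kind = EventKind.HEEL_STRIKE if labeled.is_high[i] else EventKind.TOE_OFF
        events.append(GaitEvent(kind=kind, index=nadir, time=nadir / fs))
    return events


def compute_stride_times(events: list[GaitEvent], fs: float,
                         stride_bounds_s: tuple[float, float] = (0.4, 2.5)
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Stride times from consecutive heel strikes.

    ``stride_time[i] = (hs_index[i+1] - hs_index[i]) / fs``. Values outside
    the physiologic plausibility bounds are dropped (count returned).

    Returns ``(stride_times, start_times, end_times, n_dropped)``.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 heel strikes.
    """
    hs = np.array([e.index for e in events if e.kind is EventKind.HEEL_STRIKE])
    if len(hs) < 2:
        raise InsufficientDataError(f"only {len(hs)} heel strikes; need at least 2")
    strides = np.diff(hs) / fs
    lo, hi = stride_bounds_s
    keep = (strides > lo) & (strides < hi)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d stride(s) outside plausibility bounds (%g, %g) s",
                    n_dropped, lo, hi)
    return (strides[keep], hs[:-1][keep] / fs, hs[1:][keep] / fs, n_dropped)


def extract_gait_events(az_filt: np.ndarray, fs: float,
                        config: PipelineConfig | None = None,
                        meta: TrialMeta | None = None) -> GaitEventSequence:
    """Full event-detection chain: peaks -> labels -> nadirs -> stride times."""
    config = config or PipelineConfig()
    peaks = detect_peaks(az_filt, fs,
                         prominence_frac=config.events_prominence_frac,
                         min_separation_s=config.events_min_separation_s)
    labeled = classify_peaks(peaks)
    events = locate_events(az_filt, labeled, fs)
    strides, starts, ends, n_dropped = compute_stride_times(
        events, fs, config.stride_bounds_s)
    return GaitEventSequence(
        events=events,
        fs=fs,
        stride_times=strides,
        stride_start_times=starts,
        stride_end_times=ends,
        excluded=np.zeros(len(strides), dtype=bool),
        n_dropped_implausible=n_dropped,
        n_repaired_peaks=labeled.n_repaired,
        meta=meta,
    )
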