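"""Heartbeat intervals from the ballistocardiogram and cyclic variation
of heart rate (CVHR).

Sleep apnea episodes are accompanied by a bradycardia-tachycardia pattern:
the inter-beat interval tachogram shows transient *dips* (interval minima)
recurring quasi-periodically with the apnea cycle.  Fcv is the frequency of
such cyclic dips per hour of total recording time.

Beat detection uses an energy-envelope peak picker on the 4-11 Hz
ballistocardiogram component with an adaptive threshold and a 0.4-s
refractory period; interval editing rejects physiologically implausible
intervals (outside 300-2000 ms or deviating more than 30% from a 7-beat
running median).  CVHR is then scored on a 2-Hz resampled tachogram: dips
are interval minima whose prominence exceeds an adaptive multiple of the
local variability and whose width is 10-120 s; trains are runs of three or
more consecutive dips with quasi-regular spacing (25-130 s, neighbouring
spacing ratio within [0.5, 2]).  Only dips belonging to trains count
towards Fcv.  The same machinery accepts an externally measured R-R
interval series (e.g. from the polysomnogram ECG) for an ECG-based Fcv.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import (
    DomainError,
    InsufficientDataError,
    LengthError,
    OrderingError,
    ParseError,
)

#: Physiologically valid inter-beat interval range, ms.
INTERVAL_RANGE_MS = (300.0, 2000.0)
#: Maximum relative deviation from the 7-beat running median.
MEDIAN_DEVIATION_FRACTION = 0.30
RUNNING_MEDIAN_BEATS = 7

#: Beat-picker constants.
REFRACTORY_S = 0.4
ENERGY_WINDOW_S = 0.2
PEAK_THRESHOLD_FRACTION = 0.3  # of the 95th percentile of the energy envelope

#: CVHR constants (exposed through CvhrParams).
TACHOGRAM_HZ = 2.0


@dataclass(frozen=True)
class CvhrParams:
    """Constants of the cyclic-dip detector.

    Defaults follow the published description of auto-correlated cyclic dip
    scoring: a 2-Hz tachogram, dips 10-120 s wide recurring every 25-130 s,
    at least three dips per train with neighbouring spacing ratio in
    [0.5, 2].  The prominence threshold adapts to the tachogram's own
    variability (``prominence_sigma`` robust standard deviations, floored at
    ``min_prominence_ms``).
    """

    dip_width_range_s: tuple = (10.0, 120.0)
    train_spacing_range_s: tuple = (25.0, 130.0)
    min_dips_per_train: int = 3
    spacing_ratio_range: tuple = (0.5, 2.0)
    min_prominence_ms: float = 100.0
    prominence_sigma: float = 4.0
    smooth_window_s: float = 10.0
    #: Window of the running median used only to estimate jitter noise; it is
    #: short enough to track the dips themselves, so the estimate reflects
    #: beat-to-beat variability rather than the cyclic dip structure.
    noise_window_s: float = 15.0


@dataclass
class HeartbeatSeries:
    """Beat times and successive inter-beat intervals with quality flags.

    ``intervals_ms[i]`` spans ``beat_times_s[i] .. beat_times_s[i+1]``;
    ``valid[i]`` is true for intervals that survive the editing rules.
    """

    beat_times_s: np.ndarray
    intervals_ms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=np.float64)
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times_s.size)

    def shifted(self, offset_s: float) -> "HeartbeatSeries":
        return HeartbeatSeries(
            self.beat_times_s + offset_s, self.intervals_ms.copy(), self.valid.copy()
        )


@dataclass
class CVHRResult:
    """Detected cyclic heart-rate dips and their frequency (Fcv)."""

    dip_times_s: np.ndarray
    trains: List[np.ndarray]  # each an array of dip times belonging to one train
    trt_hours: float

    @property
    def n_cyclic_dips(self) -> int:
        if not self.trains:
            return 0
        # a dip shared by two adjacent trains is counted once
        return int(np.unique(np.concatenate(self.trains)).size)

    @property
    def fcv(self) -> float:
        return self.n_cyclic_dips / self.trt_hours


def _edit_intervals(intervals_ms: np.ndarray) -> np.ndarray:
    """Quality flags per interval: range rule plus running-median rule."""
    intervals_ms = np.asarray(intervals_ms, dtype=np.float64)
    if intervals_ms.size == 0:
        return np.zeros(0, dtype=bool)
    lo, hi = INTERVAL_RANGE_MS
    in_range = (intervals_ms >= lo) & (intervals_ms <= hi)
    if intervals_ms.size >= RUNNING_MEDIAN_BEATS:
        running = median_filter(intervals_ms, size=RUNNING_MEDIAN_BEATS, mode="nearest")
    else:
        running = np.full_like(intervals_ms, np.median(intervals_ms))
    near_median = np.abs(intervals_ms - running) <= MEDIAN_DEVIATION_FRACTION * running
    return in_range & near_median


def _series_from_beats(beat_times_s: np.ndarray) -> HeartbeatSeries:
    beat_times_s = np.asarray(beat_times_s, dtype=np.float64)
    intervals = np.diff(beat_times_s) * 1000.0
    return HeartbeatSeries(beat_times_s, intervals, _edit_intervals(intervals))


def detect_heartbeats(
    bcg: np.ndarray,
    rate: float,
    mask: Optional[np.ndarray] = None,
) -> HeartbeatSeries:
    """Locate heartbeats in the ballistocardiogram component.

    Beats are peaks of the smoothed BCG energy envelope above an adaptive
    threshold (a fixed fraction of the envelope's 95th percentile) with a
    0.4-s refractory period.  Samples flagged by the movement mask produce
    no beats.
    """
    bcg = np.asarray(bcg, dtype=np.float64)
    if bcg.size < 10 * rate:
        raise LengthError(
            f"ballistocardiogram of {bcg.size / rate:.1f} s is shorter than the 10 s minimum"
        )
    window = max(1, int(round(ENERGY_WINDOW_S * rate)))
    power = uniform_filter1d(np.square(bcg), size=window, mode="nearest")
    envelope = np.sqrt(np.maximum(power, 0.0))  # moving sum may cancel to ~-0
    scale = float(np.percentile(envelope, 95))
    if scale <= 0:
        return _series_from_beats(np.zeros(0))
    threshold = PEAK_THRESHOLD_FRACTION * scale
    peaks, _ = sps.find_peaks(
        envelope, height=threshold, distance=max(1, int(round(REFRACTORY_S * rate)))
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        peaks = peaks[~mask[peaks]]
    return _series_from_beats(peaks / rate)


def read_interval_series(path: Union[str, Path]) -> HeartbeatSeries:
    """Read a two-column text file ``beat_time_s interval_ms``.

    The same editing rules used for ballistocardiogram intervals are applied
    to the parsed series.  Times must be strictly increasing.
    """
    path = Path(path)
    times: List[float] = []
    intervals: List[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ParseError(f"{path}: expected two columns on row {lineno}")
            try:
                times.append(float(fields[0]))
                intervals.append(float(fields[1]))
            except ValueError:
                raise ParseError(f"{path}: non-numeric value on row {lineno}") from None
    times_arr = np.asarray(times)
    if times_arr.size >= 2 and np.any(np.diff(times_arr) <= 0):
        bad = int(np.flatnonzero(np.diff(times_arr) <= 0)[0]) + 2
        raise OrderingError(f"{path}: beat times not strictly increasing at entry {bad}")
    intervals_arr = np.asarray(intervals)
    # range rule applies to the listed intervals even when the series is short
    return HeartbeatSeries(times_arr, intervals_arr, _edit_intervals(intervals_arr))


def detect_cvhr(
    series: HeartbeatSeries,
    trt_hours: float,
    params: CvhrParams | None = None,
) -> CVHRResult:
    """Score cyclic variation of heart rate on an interval series.

    The valid intervals are resampled to an evenly spaced 2-Hz tachogram and
    lightly smoothed.  Dips are tachogram minima with adaptive prominence
    and plausible width; trains are quasi-regular runs of at least three
    dips.  ``fcv`` counts only dips belonging to trains, per hour of TRT.
    """
    params = params or CvhrParams()
    if not (trt_hours > 0):
        raise DomainError(f"trt_hours must be > 0, got {trt_hours}")

    valid = series.valid
    if series.intervals_ms.size == 0 or valid.sum() < 2:
        raise InsufficientDataError("no valid heartbeat intervals")
    # each interval is anchored at the time of its terminating beat; an
    # externally read series lists that beat time directly per interval
    if series.intervals_ms.size == series.beat_times_s.size:
        anchor_times = series.beat_times_s[valid]
    else:
        anchor_times = series.beat_times_s[1:][valid]
    anchor_vals = series.intervals_ms[valid]
    span = anchor_times[-1] - anchor_times[0]
    if span < 600.0:
        raise InsufficientDataError(
            f"only {span:.0f} s of valid intervals; need at least 600 s"
        )

    fs = TACHOGRAM_HZ
    t = np.arange(anchor_times[0], anchor_times[-1], 1.0 / fs)
    tach = np.interp(t, anchor_times, anchor_vals)
    smooth = uniform_filter1d(
        tach, size=max(1, int(round(params.smooth_window_s * fs))), mode="nearest"
    )

    baseline = median_filter(
        smooth, size=max(3, int(round(params.noise_window_s * fs)) | 1), mode="nearest"
    )
    residual = smooth - baseline
    mad = float(np.median(np.abs(residual - np.median(residual))))
    robust_sd = 1.4826 * mad
    prominence = max(params.min_prominence_ms, params.prominence_sigma * robust_sd)

    wmin, wmax = params.dip_width_range_s
    dips, _props = sps.find_peaks(
        -smooth,
        prominence=prominence,
        width=(wmin * fs, wmax * fs),
        rel_height=0.9,
    )
    dip_times = t[dips]

    trains = _group_trains(dip_times, params)
    return CVHRResult(dip_times_s=dip_times, trains=trains, trt_hours=trt_hours)


def _group_trains(dip_times: np.ndarray, params: CvhrParams) -> List[np.ndarray]:
    """Group dips into quasi-regular trains of >= min_dips_per_train."""
    trains: List[np.ndarray] = []
    n = len(dip_times)
    if n < params.min_dips_per_train:
        return trains
    s_lo, s_hi = params.train_spacing_range_s
    r_lo, r_hi = params.spacing_ratio_range
    spacing = np.diff(dip_times)
    spacing_ok = (spacing >= s_lo) & (spacing <= s_hi)

    start = 0
    i = 0
    while i < n - 1:
        if not spacing_ok[i]:
            _maybe_add_train(trains, dip_times, start, i, params)
            start = i + 1
        elif i > start and spacing_ok[i - 1]:
            ratio = spacing[i] / spacing[i - 1]
            if not (r_lo <= ratio <= r_hi):
                _maybe_add_train(trains, dip_times, start, i, params)
                start = i
        i += 1
    _maybe_add_train(trains, dip_times, start, n - 1, params)
    return trains


def _maybe_add_train(trains, dip_times, start, last, params) -> None:
    if last - start + 1 >= params.min_dips_per_train:
        trains.append(dip_times[start : last + 1])


def run_fcv(
    record,
    trt_hours: Optional[float] = None,
    params: CvhrParams | None = None,
    components=None,
) -> CVHRResult:
    """Convenience pipeline: record -> BCG component -> beats -> CVHR."""
    from .decompose import extract_components

    comps = components or extract_components(record)
    series = detect_heartbeats(comps.bcg, record.sampling_rate, comps.movement_mask)
    return detect_cvhr(series, trt_hours or record.trt_hours, params)
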