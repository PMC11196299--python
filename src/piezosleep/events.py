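"""Respiratory-event detection and the respiratory event index (REI).

The detector works on the respiration-band component of the micromotion
signal:

1. rectify and log-transform the respiratory amplitude, ``ln(|x| + eps)``;
2. compute two upper envelopes of the log amplitude on a regular time grid —
   a *fast* envelope (short window, breath-by-breath amplitude) and a *slow*
   envelope (long window, local trend of sub-maximum amplitude), both as the
   95th-percentile point of the window (nearest-rank), which discards
   outliers with an incidence below 5%;
3. detect periods where the fast envelope separates downward from the slow
   envelope by more than a depth threshold expressed as a relative amplitude
   reduction: a ``d``-percent reduction corresponds to a log-domain
   separation of ``-ln(1 - d/100)`` (30% -> ln(1.43) ~ 0.357);
4. keep periods whose duration lies within the duration criteria
   (default 10-70 s) as respiratory events;
5. report REI = events per hour of total recording time.

Because the threshold is a *relative* reduction measured in the log domain,
detection is invariant to the overall amplitude scale, which changes with
body posture and sensor coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .decompose import ComponentSignals, FilterBands, extract_components
from .errors import ConfigurationError, DomainError, LengthError
from .io import MicromotionRecord

#: Guard added inside the log transform, in sensor units.  One least
#: significant ADC count: prevents -inf and is negligible against
#: physiological respiratory amplitudes.
LOG_EPSILON = 1.0


@dataclass(frozen=True)
class EnvelopeParams:
    """Windows for the fast/slow upper envelopes of the log amplitude.

    The fast window spans a few breaths (default 10 s at 15 breaths/min);
    the slow window spans the pre-event baseline across one or two
    apnea-hypopnea cycles (default 120 s).  Envelopes are evaluated every
    ``grid_step_s`` seconds on centered windows.
    """

    fast_window_s: float = 10.0
    slow_window_s: float = 120.0
    percentile: float = 0.95
    grid_step_s: float = 1.0
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.fast_window_s < self.slow_window_s):
            raise ConfigurationError(
                f"need 0 < fast window < slow window, got "
                f"{self.fast_window_s} / {self.slow_window_s}"
            )
        if not (0 < self.percentile < 1):
            raise ConfigurationError(f"percentile must be in (0, 1), got {self.percentile}")
        if not (self.grid_step_s > 0):
            raise ConfigurationError("grid_step_s must be > 0")


@dataclass
class EnvelopePair:
    """Fast and slow envelopes on a common, regularly spaced time grid.

    ``valid`` is false at grid points whose windows are dominated by the
    movement mask (or truncated at the recording edge); such points carry
    NaN envelope values and never contribute to events.
    """

    times: np.ndarray
    fast: np.ndarray
    slow: np.ndarray
    valid: np.ndarray
    grid_step_s: float
    trt_seconds: float

    @property
    def trt_hours(self) -> float:
        return self.trt_seconds / 3600.0


@dataclass(frozen=True)
class DetectionParams:
    """Depth threshold and duration criteria for event detection."""

    depth_percent: float = 30.0
    min_duration_s: float = 10.0
    max_duration_s: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.depth_percent < 100):
            raise ConfigurationError(
                f"depth_percent must be in (0, 100), got {self.depth_percent}"
            )
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ConfigurationError(
                f"need 0 < min duration < max duration, got "
                f"{self.min_duration_s} / {self.max_duration_s}"
            )

    @property
    def log_threshold(self) -> float:
        """Depth threshold in the log-amplitude domain, -ln(1 - depth/100)."""
        return -math.log1p(-self.depth_percent / 100.0)


@dataclass(frozen=True)
class RespiratoryEvent:
    """One detected respiratory event (start inclusive, end exclusive)."""

    start_s: float
    end_s: float
    max_depth_log: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class REIResult:
    """Detected events and the events-per-hour-of-TRT summary."""

    events: List[RespiratoryEvent]
    trt_hours: float

    @property
    def rei(self) -> float:
        return len(self.events) / self.trt_hours


def log_amplitude(
    respiration: np.ndarray, sampling_rate: float | None = None, eps: float = LOG_EPSILON
) -> np.ndarray:
    """Rectified, natural-log-transformed respiratory amplitude.

    ``ln(|x| + eps)`` per sample; ``eps`` defaults to one sensor unit.
    """
    return np.log(np.abs(np.asarray(respiration, dtype=np.float64)) + eps)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p*m)-th smallest of m values."""
    m = len(values)
    if m == 0:
        raise DomainError("percentile of an empty window")
    k = max(1, math.ceil(percentile * m))
    return float(np.partition(np.asarray(values, dtype=np.float64), k - 1)[k - 1])


def compute_envelopes(
    logamp: np.ndarray,
    mask: Optional[np.ndarray],
    rate: float,
    params: EnvelopeParams | None = None,
) -> EnvelopePair:
    """Windowed 95th-percentile envelopes of the log amplitude.

    At each grid time ``t`` the fast (slow) envelope is the nearest-rank
    percentile of the unmasked log-amplitude samples in the centered fast
    (slow) window.  A grid point is valid only when at least
    ``min_valid_fraction`` of each nominal window is unmasked and inside
    the recording.
    """
    params = params or EnvelopeParams()
    logamp = np.asarray(logamp, dtype=np.float64)
    n = logamp.size
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != logamp.shape:
        raise DomainError("logamp and mask must have equal length")
    trt_seconds = n / rate
    if trt_seconds <= params.slow_window_s:
        raise LengthError(
            f"recording of {trt_seconds:.1f} s is not longer than the slow "
            f"window ({params.slow_window_s:.1f} s)"
        )

    step = params.grid_step_s
    n_grid = int(math.floor((n - 1) / (step * rate))) + 1
    times = np.arange(n_grid) * step
    centers = np.round(times * rate).astype(np.int64)

    half_fast = int(round(params.fast_window_s * rate / 2.0))
    half_slow = int(round(params.slow_window_s * rate / 2.0))
    nominal_fast = 2 * half_fast + 1
    nominal_slow = 2 * half_slow + 1

    cum_mask = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
    any_masked = bool(cum_mask[-1])

    fast = np.full(n_grid, np.nan)
    slow = np.full(n_grid, np.nan)
    valid = np.zeros(n_grid, dtype=bool)

    for g in range(n_grid):
        c = centers[g]
        point_ok = True
        for half, nominal, out in (
            (half_fast, nominal_fast, fast),
            (half_slow, nominal_slow, slow),
        ):
            i0 = max(0, c - half)
            i1 = min(n, c + half + 1)
            n_masked = cum_mask[i1] - cum_mask[i0]
            n_unmasked = (i1 - i0) - n_masked
            if n_unmasked < params.min_valid_fraction * nominal or n_unmasked == 0:
                point_ok = False
                continue
            window = logamp[i0:i1]
            if any_masked and n_masked:
                window = window[~mask[i0:i1]]
            out[g] = nearest_rank_percentile(window, params.percentile)
        valid[g] = point_ok

    fast[~valid] = np.nan
    slow[~valid] = np.nan
    return EnvelopePair(
        times=times,
        fast=fast,
        slow=slow,
        valid=valid,
        grid_step_s=step,
        trt_seconds=trt_seconds,
    )


def detect_events(
    env: EnvelopePair, params: DetectionParams | None = None
) -> List[RespiratoryEvent]:
    """Threshold the slow-fast envelope separation into respiratory events.

    Maximal runs of consecutive *valid* grid points with
    ``slow - fast >= -ln(1 - depth/100)`` are candidate periods; runs
    interrupted by invalid (movement-masked) points are split.  Candidates
    whose duration (run length x grid step) lies within
    ``[min_duration_s, max_duration_s]`` become events; longer runs are
    rejected whole rather than split.
    """
    params = params or DetectionParams()
    if env.times.size == 0:
        return []
    if env.grid_step_s > params.min_duration_s / 5.0:
        raise ConfigurationError(
            f"grid step {env.grid_step_s} s too coarse for a minimum duration "
            f"of {params.min_duration_s} s (need step <= min/5)"
        )

    step = env.grid_step_s
    threshold = params.log_threshold
    with np.errstate(invalid="ignore"):
        separation = env.slow - env.fast
        above = env.valid & (separation >= threshold)

    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    events: List[RespiratoryEvent] = []
    for i, j in zip(edges[::2], edges[1::2]):  # run covers grid points [i, j)
        duration = (j - i) * step
        if params.min_duration_s <= duration <= params.max_duration_s:
            events.append(
                RespiratoryEvent(
                    start_s=float(env.times[i]),
                    end_s=float(env.times[j - 1] + step),
                    max_depth_log=float(np.max(separation[i:j])),
                )
            )
    return events


def compute_rei(events: Sequence[RespiratoryEvent], trt_hours: float) -> REIResult:
    """Events per hour of total recording time."""
    if not (trt_hours > 0):
        raise DomainError(f"trt_hours must be > 0, got {trt_hours}")
    return REIResult(events=list(events), trt_hours=trt_hours)


def run_detection(
    record: MicromotionRecord,
    bands: FilterBands | None = None,
    env_params: EnvelopeParams | None = None,
    det_params: DetectionParams | None = None,
    components: ComponentSignals | None = None,
) -> REIResult:
    """Full pipeline: decompose -> log amplitude -> envelopes -> events -> REI.

    ``components`` may be supplied to reuse an existing decomposition.
    Deterministic for fixed input and parameters.
    """
    comps = components or extract_components(record, bands)
    logamp = log_amplitude(comps.respiration)
    env = compute_envelopes(logamp, comps.movement_mask, record.sampling_rate, env_params)
    events = detect_events(env, det_params)
    return compute_rei(events, record.trt_hours)
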