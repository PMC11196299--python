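"""Grid search for the detector's depth threshold and duration criteria.

The detection parameters are calibrated on a training cohort by exhaustive
grid search: for every (depth, min duration, max duration) cell, REI is
computed per subject and the Pearson correlation between REI and the
reference AHI (TRT denominator) is recorded; the cell with the highest
correlation wins.  Depth is searched in 1% increments and durations at 10-s
intervals.  Envelopes do not depend on the detection parameters, so they
are computed once per subject and reused across all grid cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np

from .decompose import FilterBands, extract_components
from .errors import ConfigurationError, UndefinedCorrelationError
from .events import (
    DetectionParams,
    EnvelopePair,
    EnvelopeParams,
    compute_envelopes,
    detect_events,
    log_amplitude,
)
from .io import MicromotionRecord


@dataclass(frozen=True)
class GridSpec:
    """Search grid: depth in 1% steps, duration candidates in 10-s steps."""

    depth_range_percent: Tuple[float, float] = (10.0, 60.0)
    min_dur_candidates_s: Tuple[float, ...] = (10.0, 20.0, 30.0)
    max_dur_candidates_s: Tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0)
    depth_step_percent: float = 1.0

    def depths(self) -> np.ndarray:
        low, high = self.depth_range_percent
        if not (0 < low <= high < 100) or self.depth_step_percent <= 0:
            raise ConfigurationError(f"invalid depth range {self.depth_range_percent}")
        n = int(round((high - low) / self.depth_step_percent)) + 1
        return low + self.depth_step_percent * np.arange(n)

    def cells(self) -> List[DetectionParams]:
        """All grid cells with min < max, in deterministic scan order."""
        cells = [
            DetectionParams(depth_percent=float(d), min_duration_s=lo, max_duration_s=hi)
            for d in self.depths()
            for lo, hi in itertools.product(
                self.min_dur_candidates_s, self.max_dur_candidates_s
            )
            if lo < hi
        ]
        if not cells:
            raise ConfigurationError("empty parameter grid")
        return cells


@dataclass
class GridSearchResult:
    best_params: DetectionParams
    best_r: float
    trace: List[Tuple[DetectionParams, float]]


CohortItem = Tuple[Union[MicromotionRecord, EnvelopePair], float]


def prepare_envelopes(
    record: MicromotionRecord,
    bands: FilterBands | None = None,
    env_params: EnvelopeParams | None = None,
) -> EnvelopePair:
    """Decompose a record and compute its (parameter-independent) envelopes."""
    comps = extract_components(record, bands)
    logamp = log_amplitude(comps.respiration)
    return compute_envelopes(logamp, comps.movement_mask, record.sampling_rate, env_params)


def grid_search(
    cohort: Sequence[CohortItem],
    spec: GridSpec | None = None,
    bands: FilterBands | None = None,
    env_params: EnvelopeParams | None = None,
) -> GridSearchResult:
    """Exhaustive search maximising Pearson r(REI, AHI_TRT).

    ``cohort`` pairs each subject's recording (or precomputed envelope pair)
    with the reference AHI.  Ties in r are broken deterministically by
    smaller depth, then wider duration band, then scan order.
    """
    spec = spec or GridSpec()
    if len(cohort) < 3:
        raise ConfigurationError(f"cohort of {len(cohort)} subjects; need at least 3")
    ahi = np.asarray([a for _, a in cohort], dtype=np.float64)
    if np.ptp(ahi) == 0:
        raise UndefinedCorrelationError("reference AHI is constant across the cohort")

    envelopes = [
        item if isinstance(item, EnvelopePair) else prepare_envelopes(item, bands, env_params)
        for item, _ in cohort
    ]
    trt_hours = np.asarray([e.trt_hours for e in envelopes])

    trace: List[Tuple[DetectionParams, float]] = []
    best_idx = -1
    best_key = None
    for idx, params in enumerate(spec.cells()):
        rei = np.asarray(
            [len(detect_events(env, params)) for env in envelopes], dtype=np.float64
        ) / trt_hours
        if np.ptp(rei) == 0:
            r = float("-inf")  # degenerate cell: REI constant, correlation undefined
        else:
            r = float(np.corrcoef(rei, ahi)[0, 1])
        trace.append((params, r))
        key = (
            -r,
            params.depth_percent,
            -(params.max_duration_s - params.min_duration_s),
            idx,
        )
        if best_key is None or key < best_key:
            best_key = key
            best_idx = idx

    best_params, best_r = trace[best_idx]
    return GridSearchResult(best_params=best_params, best_r=best_r, trace=trace)
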