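"""Sensor-recording and subject-metadata I/O.

The sheet-sensor device digitises bed micromotion at 100 Hz with a 24-bit
dynamic range and writes one integer amplitude per CSV row.  This module
provides the in-memory record type, readers/writers for that format, the
subject metadata table, and the clinical AHI severity banding
(normal < 5, mild 5-15, moderate 15-30, severe >= 30 events/h of TST).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    ParseError,
    RangeError,
)

#: Signed 24-bit ADC limits of the sheet-sensor device.
ADC_MIN = -(2**23)
ADC_MAX = 2**23 - 1

#: AHI (events/h of TST) boundaries between severity classes; boundary
#: values belong to the higher class ("AHI >= 15", "AHI >= 30").
AHI_SEVERITY_BOUNDS = (5.0, 15.0, 30.0)


class SeverityClass(enum.IntEnum):
    """Ordinal sleep-apnea severity classes."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


def severity_class(ahi_tst: float) -> SeverityClass:
    """Map a reference AHI (TST denominator) to its severity class.

    Boundary values (5, 15, 30) map to the higher class.
    """
    if not math.isfinite(ahi_tst) or ahi_tst < 0:
        raise DomainError(f"AHI must be a finite non-negative rate, got {ahi_tst!r}")
    if ahi_tst < AHI_SEVERITY_BOUNDS[0]:
        return SeverityClass.NORMAL
    if ahi_tst < AHI_SEVERITY_BOUNDS[1]:
        return SeverityClass.MILD
    if ahi_tst < AHI_SEVERITY_BOUNDS[2]:
        return SeverityClass.MODERATE
    return SeverityClass.SEVERE


@dataclass(frozen=True)
class MicromotionRecord:
    """A single-channel micromotion recording.

    Parameters
    ----------
    samples
        Amplitude sequence in raw sensor units.  Values must lie within the
        signed 24-bit range of the device ADC.
    sampling_rate
        Sampling frequency in Hz (device default 100).
    start_time
        Optional wall-clock timestamp of the first sample.
    """

    samples: np.ndarray
    sampling_rate: float = 100.0
    start_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1:
            raise DomainError("samples must be one-dimensional")
        object.__setattr__(self, "samples", samples)
        if not (self.sampling_rate > 0):
            raise DomainError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if samples.size:
            lo = samples.min()
            hi = samples.max()
            if lo < ADC_MIN or hi > ADC_MAX:
                raise RangeError(
                    f"sample values span [{lo}, {hi}], outside the 24-bit range "
                    f"[{ADC_MIN}, {ADC_MAX}]"
                )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def trt_seconds(self) -> float:
        """Total recording time in seconds (n / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def trt_hours(self) -> float:
        return self.trt_seconds / 3600.0


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject reference metadata from the polysomnogram."""

    subject_id: str
    ahi_trt: float
    ahi_tst: float
    plm_index: float = 0.0
    group: str = "training"

    def __post_init__(self) -> None:
        for name in ("ahi_trt", "ahi_tst", "plm_index"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise DomainError(f"{name} must be a finite non-negative rate, got {value}")

    @property
    def severity(self) -> SeverityClass:
        return severity_class(self.ahi_tst)


def _looks_like_timestamp(token: str) -> bool:
    try:
        datetime.fromisoformat(token)
        return True
    except ValueError:
        return False


def _parse_int(token: str) -> Optional[int]:
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        # accept integer-valued floats such as "100.0"
        try:
            value = float(token)
        except ValueError:
            return None
        if value.is_integer():
            return int(value)
        return None


def read_micromotion_csv(
    path: Union[str, Path], sampling_rate: float = 100.0
) -> MicromotionRecord:
    """Read a sheet-sensor CSV recording.

    The accepted dialect is one integer amplitude per row, UTF-8, with an
    optional single header line and an optional leading ISO-8601 timestamp
    column (auto-detected from the first data row).

    Raises
    ------
    EmptyInputError
        If the file contains no data rows.
    ParseError
        If a payload row is non-numeric; the message names the row number.
    RangeError
        If a value falls outside the signed 24-bit range.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh)]

    # Drop trailing/interior blank lines but remember original numbering.
    numbered = [(i + 1, row) for i, row in enumerate(rows) if any(f.strip() for f in row)]
    if not numbered:
        raise EmptyInputError(f"{path}: no data rows")

    start_row = 0
    first_fields = numbered[0][1]
    value_token = first_fields[-1]
    has_header = _parse_int(value_token) is None and not _looks_like_timestamp(value_token)
    if has_header:
        start_row = 1
        if len(numbered) == 1:
            raise EmptyInputError(f"{path}: header only, no data rows")

    first_data = numbered[start_row][1]
    has_timestamp = len(first_data) >= 2 and _looks_like_timestamp(first_data[0])

    start_time: Optional[datetime] = None
    values = np.empty(len(numbered) - start_row, dtype=np.int64)
    for k, (lineno, fields) in enumerate(numbered[start_row:]):
        token = fields[-1]
        value = _parse_int(token)
        if value is None:
            raise ParseError(f"{path}: non-numeric value {token!r} on row {lineno}")
        if value < ADC_MIN or value > ADC_MAX:
            raise RangeError(
                f"{path}: value {value} on row {lineno} outside 24-bit range "
                f"[{ADC_MIN}, {ADC_MAX}]"
            )
        values[k] = value
        if k == 0 and has_timestamp:
            start_time = datetime.fromisoformat(fields[0])

    return MicromotionRecord(
        samples=values.astype(np.int32),
        sampling_rate=sampling_rate,
        start_time=start_time,
    )


def write_micromotion_csv(record: MicromotionRecord, path: Union[str, Path]) -> None:
    """Write a recording in the one-integer-per-row dialect (no header)."""
    samples = np.rint(np.asarray(record.samples)).astype(np.int64)
    np.savetxt(path, samples, fmt="%d")


def read_subject_meta(path: Union[str, Path]) -> list[SubjectMeta]:
    """Read the subject metadata table.

    Expected CSV header columns: subject_id, ahi_trt, ahi_tst, plm_index, group.
    """
    frame = pd.read_csv(path)
    required = {"subject_id", "ahi_trt", "ahi_tst"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = []
    for row in frame.itertuples(index=False):
        metas.append(
            SubjectMeta(
                subject_id=str(row.subject_id),
                ahi_trt=float(row.ahi_trt),
                ahi_tst=float(row.ahi_tst),
                plm_index=float(getattr(row, "plm_index", 0.0) or 0.0),
                group=str(getattr(row, "group", "training")),
            )
        )
    return metas


def write_subject_meta(metas: Sequence[SubjectMeta], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metas],
            "ahi_trt": [m.ahi_trt for m in metas],
            "ahi_tst": [m.ahi_tst for m in metas],
            "plm_index": [m.plm_index for m in metas],
            "group": [m.group for m in metas],
        }
    ).to_csv(path, index=False)


# --- event annotation files -------------------------------------------------

EVENT_COLUMNS = ("subject_id", "start_s", "end_s", "duration_s", "max_depth_log")


def write_events_tsv(events, subject_id: str, path: Union[str, Path]) -> None:
    """Write detected events as tab-separated text.

    Columns: subject_id, start_s, end_s, duration_s, max_depth_log
    (start inclusive, end exclusive, seconds from recording start).
    """
    pd.DataFrame(
        {
            "subject_id": [subject_id] * len(events),
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "max_depth_log": [e.max_depth_log for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing event columns {sorted(missing)}")
    return frame
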