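"""Core data types for overnight oximetry sessions and clinical records.

An :class:`OximetrySession` holds one participant-night of 1 Hz SpO2 and
heart-rate samples exactly as exported by a wrist oximeter (including
out-of-range sentinel codes such as 500, which are preserved for the
artefact filter to handle).  Sessions are stored on disk as plain CSV with
the header ``elapsed_s,spo2,hr``, one row per second.

Clinical side-tables — Lake Louise symptom scores, morning spot oximetry
and arterialized capillary SaO2 — are small CSV tables with typed readers
and writers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InputDomainError,
    MissingDataError,
    ParseError,
)

SESSION_HEADER = ["elapsed_s", "spo2", "hr"]

MORNING = "morning"
EVENING = "evening"


@dataclass
class OximetrySession:
    """One participant-night of 1 Hz oximetry.

    ``spo2`` and ``hr`` are aligned 1:1; sample ``i`` was recorded ``i``
    seconds after the start of the recording.  ``valid_mask`` is all-True
    on load and updated in place by the artefact filter.  ``hr`` may be
    None for SpO2-only sessions; every SpO2 operation still runs.
    """

    participant_id: str
    night_label: str
    altitude_m: float
    spo2: np.ndarray
    hr: np.ndarray | None = None
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    start_time: str | None = None
    sample_rate_hz: int = 1

    def __post_init__(self):
        self.spo2 = np.asarray(self.spo2)
        if self.spo2.size < 1:
            raise EmptyInputError("session must contain at least one sample")
        if self.hr is not None:
            self.hr = np.asarray(self.hr)
            if self.hr.shape != self.spo2.shape:
                raise InputDomainError("hr and spo2 must be aligned 1:1")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.spo2.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.spo2.shape:
                raise InputDomainError("valid_mask must match spo2 length")
        if self.sample_rate_hz != 1:
            raise InputDomainError("only 1 Hz sessions are supported")
        if self.altitude_m < 0:
            raise InputDomainError("altitude_m must be >= 0")

    def __len__(self) -> int:
        return int(self.spo2.size)

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.night_label)


@dataclass(frozen=True)
class LLSRecord:
    """A Lake Louise symptom score recorded one morning or evening."""

    participant_id: str
    day_label: str
    time_of_day: str  # "morning" | "evening"
    total_score: int
    headache_score: int

    def __post_init__(self):
        if self.time_of_day not in (MORNING, EVENING):
            raise InputDomainError(f"time_of_day must be morning/evening, got {self.time_of_day!r}")
        if self.total_score < 0 or self.headache_score < 0:
            raise InputDomainError("LLS scores must be non-negative")
        if self.headache_score > self.total_score:
            raise InputDomainError("headache_score cannot exceed total_score")


@dataclass(frozen=True)
class CapillarySample:
    """Arterialized capillary oxygen saturation (the reference measure)."""

    participant_id: str
    day_label: str
    sao2: float

    def __post_init__(self):
        if not 0 < self.sao2 <= 100:
            raise InputDomainError("sao2 must be in (0, 100]")


@dataclass(frozen=True)
class SpotMeasurement:
    """Morning spot SpO2 averaged over ~60-90 s at the oximeter display."""

    participant_id: str
    day_label: str
    mo_spo2: float

    def __post_init__(self):
        if not 0 < self.mo_spo2 <= 100:
            raise InputDomainError("mo_spo2 must be in (0, 100]")


# ---------------------------------------------------------------------------
# session file I/O
# ---------------------------------------------------------------------------

def read_session(
    path,
    participant_id: str,
    night_label: str,
    altitude_m: float,
    start_time: str | None = None,
) -> OximetrySession:
    """Read a 1 Hz session CSV (``elapsed_s,spo2,hr``).

    Sentinel values (e.g. 500) are preserved verbatim; the returned
    session has an all-True ``valid_mask``.  Malformed rows raise
    :class:`ParseError` naming the 1-based line number.
    """
    spo2: list[int] = []
    hr: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EmptyInputError(f"{path}: empty session file") from None
        if [h.strip() for h in header] != SESSION_HEADER:
            raise ParseError(f"expected header {','.join(SESSION_HEADER)!r}", line_no=1)
        line_no = 1
        for row in reader:
            line_no += 1
            if len(row) != 3:
                raise ParseError(
                    f"expected 3 columns, found {len(row)}", line_no=line_no
                )
            try:
                elapsed = int(row[0])
                spo2.append(int(round(float(row[1]))))
                hr.append(int(round(float(row[2]))))
            except ValueError:
                raise ParseError(f"non-numeric value in {row!r}", line_no=line_no) from None
            if elapsed != line_no - 2:
                raise ParseError(
                    f"elapsed_s {elapsed} out of order (expected {line_no - 2})",
                    line_no=line_no,
                )
    if not spo2:
        raise EmptyInputError(f"{path}: session file has a header but no samples")
    return OximetrySession(
        participant_id=participant_id,
        night_label=night_label,
        altitude_m=altitude_m,
        spo2=np.asarray(spo2, dtype=np.int64),
        hr=np.asarray(hr, dtype=np.int64),
        start_time=start_time,
    )


def write_session(session: OximetrySession, path) -> None:
    """Write a session to CSV such that :func:`read_session` round-trips it."""
    hr = session.hr if session.hr is not None else np.zeros(len(session), dtype=np.int64)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_HEADER)
        writer.writerows(zip(range(len(session)), session.spo2.tolist(), hr.tolist()))


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def read_lls_table(path) -> list[LLSRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str, "day_label": str})
    return [
        LLSRecord(
            participant_id=r.participant_id,
            day_label=r.day_label,
            time_of_day=r.time_of_day,
            total_score=int(r.total_score),
            headache_score=int(r.headache_score),
        )
        for r in df.itertuples()
    ]


def write_lls_table(records: Iterable[LLSRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def read_spot_table(path) -> list[SpotMeasurement]:
    df = pd.read_csv(path, dtype={"participant_id": str, "day_label": str})
    return [
        SpotMeasurement(r.participant_id, r.day_label, float(r.mo_spo2))
        for r in df.itertuples()
    ]


def write_spot_table(records: Iterable[SpotMeasurement], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def read_capillary_table(path) -> list[CapillarySample]:
    df = pd.read_csv(path, dtype={"participant_id": str, "day_label": str})
    return [
        CapillarySample(r.participant_id, r.day_label, float(r.sao2))
        for r in df.itertuples()
    ]


def write_capillary_table(records: Iterable[CapillarySample], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Lake Louise score helpers
# ---------------------------------------------------------------------------

_DAY_RE = re.compile(r"(\d+)\s*$")


def day_sort_key(day_label: str):
    """Order day labels by trailing integer ('day10' -> 10), lexicographic fallback."""
    m = _DAY_RE.search(day_label)
    if m:
        return (0, int(m.group(1)), day_label)
    return (1, 0, day_label)


def peak_lls(records: Sequence[LLSRecord], participant_id: str) -> tuple[str, int]:
    """Return ``(day_label, total_score)`` of the participant's peak morning LLS.

    Ties are broken toward the earliest day.  The result is invariant to the
    ordering of ``records``.
    """
    mornings = [
        r for r in records
        if r.participant_id == participant_id and r.time_of_day == MORNING
    ]
    if not mornings:
        raise MissingDataError(f"no morning LLS records for participant {participant_id!r}")
    mornings.sort(key=lambda r: day_sort_key(r.day_label))
    best = max(mornings, key=lambda r: r.total_score)  # max() keeps the first maximum
    return best.day_label, best.total_score
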