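"""Artefact rejection for 1 Hz SpO2 traces.

Three criteria flag a sample: (1) SpO2 below 30%, (2) SpO2 above 100%
(device sentinels such as 500), (3) a deviation of more than 4 percentage
points from the most recent *retained* sample.  Criterion 3 uses the last
retained sample — not the raw preceding second — so that a single spike
does not cascade-flag the good sample that follows it.  Samples before the
first retained sample are exempt from criterion 3.

Flagged samples are removed, never interpolated; downstream operations see
the retained samples with their original indices, so artefact gaps remain
visible as index discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ArtefactRules
from .errors import DegenerateRecordingError, EmptyInputError
from .session import OximetrySession


@dataclass
class ArtefactReport:
    """Summary of one session's artefact filtering."""

    flagged_indices: np.ndarray
    artefact_index_pct: float
    clean_duration_s: int
    raw_duration_s: int


@dataclass
class CleanSeries:
    """Retained samples of a session with their original sample indices."""

    indices: np.ndarray
    spo2: np.ndarray
    hr: np.ndarray | None
    participant_id: str
    night_label: str
    altitude_m: float

    def __len__(self) -> int:
        return int(self.indices.size)


def _scan_flags(spo2: np.ndarray, rules: ArtefactRules) -> np.ndarray:
    """Sequential artefact scan, vectorised across clean stretches.

    Only samples that are out of range or sit after a raw step > max_step
    can change the retained/flagged state, so the scan jumps between such
    "suspect" positions and marks everything in between as retained.
    """
    n = spo2.size
    x = spo2.astype(np.float64, copy=False)
    flags = np.zeros(n, dtype=bool)
    out_of_range = (x < rules.min_spo2) | (x > rules.max_spo2)
    step = np.zeros(n, dtype=bool)
    if n > 1:
        step[1:] = np.abs(np.diff(x)) > rules.max_step
    suspects = np.flatnonzero(out_of_range | step)
    if suspects.size == 0:
        return flags

    ref: float | None = None
    i = 0
    k = 0  # pointer into suspects
    while i < n:
        v = x[i]
        if out_of_range[i] or (ref is not None and abs(v - ref) > rules.max_step):
            flags[i] = True
            i += 1
            continue
        # sample i retained; everything up to the next suspect is chained to
        # it by raw steps <= max_step and therefore also retained.
        while k < suspects.size and suspects[k] <= i:
            k += 1
        nxt = int(suspects[k]) if k < suspects.size else n
        ref = x[nxt - 1] if nxt - 1 > i else v
        i = nxt
    return flags


def flag_artefacts(
    session: OximetrySession, rules: ArtefactRules | None = None
) -> ArtefactReport:
    """Apply the three artefact criteria, updating ``session.valid_mask``.

    Returns an :class:`ArtefactReport` with the artefact index (percentage
    of raw samples flagged) and raw/clean durations in seconds.
    """
    if len(session) < 1:
        raise EmptyInputError("cannot filter an empty session")
    rules = rules or ArtefactRules()
    rules.validate()
    flags = _scan_flags(session.spo2, rules)
    session.valid_mask = ~flags
    n = len(session)
    n_flagged = int(flags.sum())
    return ArtefactReport(
        flagged_indices=np.flatnonzero(flags),
        artefact_index_pct=100.0 * n_flagged / n,
        clean_duration_s=n - n_flagged,
        raw_duration_s=n,
    )


def clean_series(session: OximetrySession) -> CleanSeries:
    """Return the retained samples (original indices preserved, no interpolation).

    :func:`flag_artefacts` must have been applied first; on a freshly loaded
    session the all-True mask simply returns every sample.
    """
    idx = np.flatnonzero(session.valid_mask)
    if idx.size == 0:
        raise DegenerateRecordingError(
            f"session {session.key}: every sample was flagged as artefact"
        )
    return CleanSeries(
        indices=idx,
        spo2=session.spo2[idx].astype(np.float64),
        hr=session.hr[idx].astype(np.float64) if session.hr is not None else None,
        participant_id=session.participant_id,
        night_label=session.night_label,
        altitude_m=session.altitude_m,
    )


def segment_bounds(indices: np.ndarray, max_gap_s: int) -> list[tuple[int, int]]:
    """Split clean-sample positions into gap-bounded segments.

    Returns ``(start, stop)`` slices into the clean arrays such that within
    a segment consecutive original indices differ by at most
    ``max_gap_s + 1`` seconds (i.e. the missing run between them is
    <= max_gap_s samples long).
    """
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > max_gap_s + 1) + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [indices.size]))
    return list(zip(starts.tolist(), stops.tolist()))
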