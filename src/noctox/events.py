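"""Desaturation-event detection and per-night roll-up.

Events are scored on the artefact-free series with a rolling baseline
(the maximum SpO2 over the preceding 20 s of contiguous clean signal).
An event opens when SpO2 falls to at least 4 points below the baseline and
closes when SpO2 recovers to within 2 points of the onset baseline
(hysteresis) or a clean-data gap longer than 5 s begins.  Events shorter
than 10 s are discarded.  All thresholds are configurable via
:class:`~noctox.config.DesaturationConfig`.

Per-night metrics follow the sleep-medicine conventions: the oxygen
desaturation index (ODI) is events per artefact-free hour and the hypoxic
burden is the summed event area (baseline minus SpO2, in %*s) converted to
%*min per artefact-free hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .artefacts import CleanSeries, segment_bounds
from .config import DesaturationConfig
from .errors import DegenerateRecordingError

log = logging.getLogger(__name__)


@dataclass
class DesaturationEvent:
    """One detected desaturation span (indices are original sample indices)."""

    onset_index: int
    end_index: int  # inclusive
    baseline: float
    nadir: float
    duration_s: int
    area_pct_s: float


@dataclass
class EventSummary:
    """Per-night desaturation metrics."""

    total_desaturations: int
    mean_duration_s: float
    odi_per_h: float
    hypoxic_burden: float  # %*min per artefact-free hour
    empty_night: bool = False


def detect_desaturations(
    clean: CleanSeries, cfg: DesaturationConfig | None = None
) -> list[DesaturationEvent]:
    """Scan the clean series for desaturation events.

    Series shorter than the baseline window yield an empty list with a
    warning rather than an error.
    """
    cfg = cfg or DesaturationConfig()
    cfg.validate()
    w = cfg.baseline_window_s
    events: list[DesaturationEvent] = []
    if len(clean) < w + 1:
        log.warning(
            "session %s/%s: %d clean samples < %d s baseline window; no events scored",
            clean.participant_id, clean.night_label, len(clean), w,
        )
        return events

    for start, stop in segment_bounds(clean.indices, cfg.max_gap_s):
        vals = clean.spo2[start:stop]
        idx = clean.indices[start:stop]
        m = vals.size
        if m < w + 1:
            continue
        # trailing max over the preceding w clean samples: baseline[t] is
        # defined for t >= w within the segment.
        win_max = np.lib.stride_tricks.sliding_window_view(vals, w).max(axis=1)
        # candidate onsets: positions t (t >= w) with a drop >= drop_pct
        cand = np.flatnonzero(vals[w:] <= win_max[: m - w] - cfg.drop_pct) + w
        pos = 0
        for t in cand:
            if t < pos:
                continue  # inside or before the previous event
            onset_baseline = float(win_max[t - w])
            j = t + 1
            recovery = onset_baseline - cfg.recovery_delta_pct
            while j < m and vals[j] < recovery:
                j += 1
            end = j - 1
            duration = int(idx[end] - idx[t] + 1)
            if duration >= cfg.min_duration_s:
                span = vals[t : end + 1]
                events.append(
                    DesaturationEvent(
                        onset_index=int(idx[t]),
                        end_index=int(idx[end]),
                        baseline=onset_baseline,
                        nadir=float(span.min()),
                        duration_s=duration,
                        area_pct_s=float(np.sum(onset_baseline - span)),
                    )
                )
            pos = end + 1
    return events


def summarize_events(
    events: list[DesaturationEvent], clean_duration_s: float
) -> EventSummary:
    """Roll events up into count, mean duration, ODI and hypoxic burden."""
    if clean_duration_s <= 0:
        raise DegenerateRecordingError("clean duration must be positive")
    hours = clean_duration_s / 3600.0
    n = len(events)
    if n == 0:
        return EventSummary(0, 0.0, 0.0, 0.0, empty_night=True)
    total_area = sum(e.area_pct_s for e in events)
    return EventSummary(
        total_desaturations=n,
        mean_duration_s=sum(e.duration_s for e in events) / n,
        odi_per_h=n / hours,
        hypoxic_burden=(total_area / 60.0) / hours,
    )
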