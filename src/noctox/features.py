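"""Per-night feature vector assembly.

Collects every overnight metric into one :class:`NightFeatures` record per
participant-night: overnight SpO2/HR means, the HR/SpO2 ratio, the
first-half/second-half change in SpO2, desaturation summary, distribution
moments, time below 80%, the lowest trailing moving averages (30 s, 3 min,
15 min, 60 min) and the first/last 15-min window means.

Half-night splits use clean-sample counts (artefact gaps would otherwise
unbalance the halves) and moving averages are trailing windows of
contiguous clean samples that never span artefact gaps longer than 5 s.
Metrics that cannot be computed (e.g. a window longer than the longest
clean run) are recorded as ``None`` — "not assessable" — rather than
raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artefacts import ArtefactReport, CleanSeries, segment_bounds
from .config import EDGE_WINDOW_S, MA_WINDOWS_S
from .distribution import SaturationDistribution, time_below
from .errors import ConsistencyError, InsufficientDataError
from .events import EventSummary
from .session import OximetrySession


@dataclass
class NightFeatures:
    """The assembled per-night feature vector."""

    participant_id: str
    night_label: str
    altitude_m: float
    ov_spo2_mean: float
    ov_spo2_sd: float
    hr_mean: float | None
    hr_sd: float | None
    hr_over_spo2: float | None
    delta_spo2: float | None
    event_summary: EventSummary
    variance: float
    skewness: float | None
    kurtosis_proper: float | None
    tst80_pct: float
    lowest_ma: dict[int, float | None]
    first15_mean: float | None
    last15_mean: float | None
    artefact_index_pct: float
    clean_duration_h: float

    def to_row(self) -> dict:
        """Flatten to one tidy table row (None -> NaN via pandas)."""
        row = {
            "participant_id": self.participant_id,
            "night_label": self.night_label,
            "altitude_m": self.altitude_m,
            "ov_spo2_mean": self.ov_spo2_mean,
            "ov_spo2_sd": self.ov_spo2_sd,
            "hr_mean": self.hr_mean,
            "hr_sd": self.hr_sd,
            "hr_over_spo2": self.hr_over_spo2,
            "delta_spo2": self.delta_spo2,
            "total_desaturations": self.event_summary.total_desaturations,
            "mean_event_duration_s": self.event_summary.mean_duration_s,
            "odi_per_h": self.event_summary.odi_per_h,
            "hypoxic_burden": self.event_summary.hypoxic_burden,
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis_proper": self.kurtosis_proper,
            "tst80_pct": self.tst80_pct,
            "first15_mean": self.first15_mean,
            "last15_mean": self.last15_mean,
            "artefact_index_pct": self.artefact_index_pct,
            "clean_duration_h": self.clean_duration_h,
        }
        for w, v in self.lowest_ma.items():
            row[f"lowest_ma_{w}s"] = v
        return row


def delta_spo2(clean: CleanSeries | np.ndarray) -> float:
    """Second-half mean minus first-half mean of the clean SpO2 samples.

    The split point is the clean-sample midpoint (``n // 2``); for odd n the
    middle sample joins the second half.
    """
    vals = clean.spo2 if isinstance(clean, CleanSeries) else np.asarray(clean, float)
    n = vals.size
    if n < 2:
        raise InsufficientDataError("delta_spo2 needs at least 2 clean samples")
    half = n // 2
    return float(vals[half:].mean() - vals[:half].mean())


def lowest_moving_average(
    clean: CleanSeries, window_s: int, max_gap_s: int = 5
) -> float | None:
    """Minimum trailing ``window_s``-sample mean over contiguous clean runs.

    Windows never span clean-data gaps longer than ``max_gap_s``.  Returns
    None (not assessable) when no contiguous run is long enough.
    """
    if window_s < 1:
        raise InsufficientDataError("window_s must be >= 1")
    best: float | None = None
    for start, stop in segment_bounds(clean.indices, max_gap_s):
        vals = clean.spo2[start:stop]
        if vals.size < window_s:
            continue
        c = np.concatenate(([0.0], np.cumsum(vals)))
        means = (c[window_s:] - c[:-window_s]) / window_s
        m = float(means.min())
        if best is None or m < best:
            best = m
    return best


def edge_window_means(
    clean: CleanSeries, window_s: int = EDGE_WINDOW_S
) -> tuple[float | None, float | None]:
    """Means over the first and last ``window_s`` clean seconds of the night.

    Returns ``(None, None)`` when the recording is shorter than the window.
    """
    vals = clean.spo2
    if vals.size < window_s:
        return None, None
    return float(vals[:window_s].mean()), float(vals[-window_s:].mean())


def assemble_features(
    session: OximetrySession,
    report: ArtefactReport,
    clean: CleanSeries,
    summary: EventSummary,
    dist: SaturationDistribution,
    ma_windows: tuple[int, ...] = MA_WINDOWS_S,
) -> NightFeatures:
    """Roll all component results for one session into a NightFeatures record.

    All components must have been computed from the same session; basic
    sample-count cross-checks guard against mixing sessions.
    """
    if report.raw_duration_s != len(session):
        raise ConsistencyError("artefact report does not match session length")
    if len(clean) != report.clean_duration_s or dist.n_samples != len(clean):
        raise ConsistencyError("clean series / distribution do not match the report")
    if clean.participant_id != session.participant_id or clean.night_label != session.night_label:
        raise ConsistencyError("clean series belongs to a different session")

    ov_mean = float(clean.spo2.mean())
    ov_sd = float(clean.spo2.std(ddof=1)) if len(clean) > 1 else 0.0
    if clean.hr is not None:
        hr_mean = float(clean.hr.mean())
        hr_sd = float(clean.hr.std(ddof=1)) if len(clean) > 1 else 0.0
        ratio = hr_mean / ov_mean if ov_mean > 0 else None
    else:
        hr_mean = hr_sd = ratio = None

    try:
        delta = delta_spo2(clean)
    except InsufficientDataError:
        delta = None

    return NightFeatures(
        participant_id=session.participant_id,
        night_label=session.night_label,
        altitude_m=session.altitude_m,
        ov_spo2_mean=ov_mean,
        ov_spo2_sd=ov_sd,
        hr_mean=hr_mean,
        hr_sd=hr_sd,
        hr_over_spo2=ratio,
        delta_spo2=delta,
        event_summary=summary,
        variance=dist.variance,
        skewness=dist.skewness,
        kurtosis_proper=dist.kurtosis_proper,
        tst80_pct=time_below(dist, 80),
        lowest_ma={w: lowest_moving_average(clean, w) for w in ma_windows},
        first15_mean=edge_window_means(clean)[0],
        last15_mean=edge_window_means(clean)[1],
        artefact_index_pct=report.artefact_index_pct,
        clean_duration_h=report.clean_duration_s / 3600.0,
    )
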