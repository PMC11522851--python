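"""Seeded synthetic expedition cohort generator.

Emulates the data streams of a high-altitude trekking study: one overnight
1 Hz SpO2/HR recording per participant-night along an ascent profile,
morning spot oximetry, morning/evening Lake Louise scores and sparse
arterialized capillary SaO2 samples, together with a ground-truth record
for every generated quantity.

The overnight signal model is a per-night baseline saturation (piecewise
linear in altitude, plus a per-participant random effect and a configurable
offset on AMS-positive nights) with AR(1) observation noise, superimposed
trapezoidal desaturation events (linear fall, nadir plateau, linear
recovery — realistic enough for detector testing while keeping analytic
areas computable) and injected sensor artefacts (sentinel 500 codes, step
spikes and sub-30% dips).

AMS-positive labels are drawn independently across participant-nights so
that the configured AMS+ saturation offset is exactly the expected group
contrast (no altitude/susceptibility composition bias); illness *severity*
(the Lake Louise totals) carries the participant-susceptibility signal that
produces negative correlations between prior-night saturation and peak
symptom scores.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
reproduces the dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .session import (
    CapillarySample,
    EVENING,
    LLSRecord,
    MORNING,
    OximetrySession,
    SpotMeasurement,
    write_capillary_table,
    write_lls_table,
    write_session,
    write_spot_table,
)

#: ascent profile analog: motorised approach then on foot, three nights at
#: the 4800 m top camp; nights are labelled by the morning that closes them.
DEFAULT_PROFILE: tuple[tuple[str, int], ...] = (
    ("day2", 1400),
    ("day3", 2000),
    ("day4", 2650),
    ("day5", 3000),
    ("day6", 3300),
    ("day7", 3300),
    ("day8", 3300),
    ("day9", 3850),
    ("day10", 3850),
    ("day11", 4800),
    ("day12", 4800),
    ("day13", 4800),
)

#: mornings with arterialized capillary sampling (after sleeping-altitude rises).
DEFAULT_CAPILLARY_DAYS: tuple[str, ...] = ("day3", "day5", "day10", "day12")


@dataclass
class GroupEffects:
    """Contrasts applied to AMS-positive participant-nights."""

    ov_spo2_offset: float = -5.0   # % saturation
    odi_multiplier: float = 1.5    # multiplies the event rate
    hr_offset: float = 4.0         # beats/min


@dataclass
class EventModel:
    """Desaturation-event generator: rate rises with altitude."""

    rate_anchors: dict = field(
        default_factory=lambda: {140: 0.5, 2000: 3.0, 3300: 12.0, 3850: 20.0, 4800: 45.0}
    )
    depth_range: tuple[float, float] = (5.0, 12.0)     # % below baseline
    duration_range: tuple[float, float] = (15.0, 40.0)  # seconds
    ramp_s: int = 5            # linear fall/recovery time (0 = square wave)
    min_separation_s: int = 25  # quiet time enforced between events


@dataclass
class SaO2BiasModel:
    """Links true overnight saturation to capillary SaO2 and spot SpO2.

    Implemented as difference-vs-average lines (the Bland-Altman geometry):
    diff = slope * (average - x_intercept), solved for the generated
    quantity, plus Gaussian noise.
    """

    ov_slope: float = 0.40
    ov_x_intercept: float = 89.8
    mo_slope: float = 0.55
    mo_x_intercept: float = 96.5
    sao2_noise_sd: float = 1.5
    spot_noise_sd: float = 1.0


@dataclass
class CohortConfig:
    """Defaults emulate an 18-participant, 12-night ascent to 4800 m."""

    n_participants: int = 18
    ascent_profile: tuple[tuple[str, int], ...] = DEFAULT_PROFILE
    ams_fraction: float = 0.10
    group_effects: GroupEffects = field(default_factory=GroupEffects)
    #: baseline (between-event) SpO2 vs altitude, piecewise linear.
    saturation_anchors: dict = field(
        default_factory=lambda: {
            140: 97.0, 1400: 96.0, 2000: 94.5, 2650: 92.5,
            3000: 91.5, 3300: 90.0, 3850: 88.0, 4800: 83.0,
        }
    )
    hr_anchors: dict = field(
        default_factory=lambda: {140: 56.0, 3300: 61.0, 3850: 63.0, 4800: 67.0}
    )
    event_model: EventModel = field(default_factory=EventModel)
    sao2_bias_model: SaO2BiasModel = field(default_factory=SaO2BiasModel)
    artefact_rate: float = 0.0075
    noise_sd: float = 1.0
    ar_coefficient: float = 0.9
    night_duration_s: int = 28800       # ~8 h
    night_duration_sd_s: float = 2700.0
    min_night_duration_s: int = 18000
    participant_sd: float = 2.0         # between-subject saturation SD (%)
    participant_hr_sd: float = 5.0
    #: correlation between participant susceptibility and (negated)
    #: saturation random effect; drives the LLS_peak ~ ov-SpO2 association.
    susceptibility_coupling: float = 0.9
    capillary_days: tuple[str, ...] = DEFAULT_CAPILLARY_DAYS
    spot_window_s: int = 75             # 60-90 s display averaging, midpoint
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not self.ascent_profile:
            raise ConfigError("ascent_profile must not be empty")
        for label, alt in self.ascent_profile:
            if alt < 0:
                raise ConfigError(f"altitude for {label} must be >= 0")
        if not 0 <= self.ams_fraction <= 1:
            raise ConfigError("ams_fraction must lie in [0, 1]")
        if not 0 <= self.artefact_rate < 1:
            raise ConfigError("artefact_rate must lie in [0, 1)")
        if self.noise_sd < 0 or not 0 <= self.ar_coefficient < 1:
            raise ConfigError("noise_sd >= 0 and 0 <= ar_coefficient < 1 required")
        if self.min_night_duration_s < 3600:
            raise ConfigError("nights shorter than an hour are not supported")


@dataclass
class Cohort:
    """Everything one expedition produces, plus generator ground truth."""

    sessions: list
    lls_records: list
    spots: list
    capillary: list
    ground_truth: dict
    config: CohortConfig


def _interp(anchors: dict, x: float) -> float:
    xs = np.array(sorted(anchors))
    ys = np.array([anchors[k] for k in sorted(anchors)], dtype=float)
    return float(np.interp(x, xs, ys))


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sd * np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], innov)


def _event_profile(depth: float, dur: int, ramp: int) -> np.ndarray:
    prof = np.full(dur, depth)
    if ramp > 0 and dur > 2 * ramp:
        slope = np.arange(1, ramp + 1) / ramp
        prof[:ramp] = depth * slope
        prof[-ramp:] = depth * slope[::-1]
    return prof


def _expected_event_drag(em: EventModel, rate_per_h: float) -> float:
    """Expected reduction of the night-mean SpO2 caused by injected events.

    The saturation anchors describe the *observed* clean-night mean, so the
    pre-event baseline is raised by this amount.  Uses the mean trapezoid
    area (depth * (duration - ramp + 1) %*s for ramped events, depth *
    duration for square waves) and the realized event rate, which is the
    nominal rate throttled by the per-event dead time (duration + enforced
    separation).
    """
    if rate_per_h <= 0:
        return 0.0
    e_depth = sum(em.depth_range) / 2.0
    e_dur = sum(em.duration_range) / 2.0
    e_area = e_depth * (e_dur - em.ramp_s + (1 if em.ramp_s > 0 else 0))
    mean_gap = e_dur + em.min_separation_s + 3600.0 / rate_per_h
    return e_area / mean_gap


def generate_night(
    config: CohortConfig,
    rng: np.random.Generator,
    participant_id: str,
    night_label: str,
    altitude_m: float,
    participant_offset: float = 0.0,
    participant_hr_offset: float = 0.0,
    ams_positive: bool = False,
    duration_s: int | None = None,
) -> tuple[OximetrySession, dict]:
    """Generate one overnight recording and its ground-truth record."""
    config.validate()
    if duration_s is None:
        duration_s = int(
            max(
                config.min_night_duration_s,
                rng.normal(config.night_duration_s, config.night_duration_sd_s),
            )
        )
    n = int(duration_s)
    ge = config.group_effects
    em = config.event_model
    rate = _interp(em.rate_anchors, altitude_m)
    if ams_positive:
        rate *= ge.odi_multiplier

    # anchors (and the AMS offset) describe the observed clean-night mean:
    # raise the pre-event baseline by the expected event drag so the
    # realized mean lands on target and the AMS+/AMS- contrast equals the
    # configured offset in expectation.
    target_mean = _interp(config.saturation_anchors, altitude_m) + participant_offset
    if ams_positive:
        target_mean += ge.ov_spo2_offset
    base = float(np.clip(target_mean + _expected_event_drag(em, rate), 40.0, 99.0))

    signal = base + _ar1(rng, n, config.noise_sd, config.ar_coefficient)

    # --- desaturation events -------------------------------------------------
    truth_events = []
    t = 30.0
    while rate > 0:
        t += rng.exponential(3600.0 / rate)
        dur = int(round(rng.uniform(*em.duration_range)))
        depth = rng.uniform(*em.depth_range)
        onset = int(round(t))
        if onset + dur + em.min_separation_s + 5 >= n:
            break
        signal[onset : onset + dur] -= _event_profile(depth, dur, em.ramp_s)
        truth_events.append({"onset": onset, "duration_s": dur, "depth": depth})
        t = onset + dur + em.min_separation_s

    spo2 = np.clip(np.floor(signal + 0.5), 31, 100).astype(np.int64)

    # ground-truth event areas from the quantized signal (what an exact
    # detector should integrate), using the quiet level just before onset.
    for ev in truth_events:
        quiet = spo2[ev["onset"] - 1]
        span = spo2[ev["onset"] : ev["onset"] + ev["duration_s"]]
        deficit = np.maximum(quiet - span, 0)
        ev["quiet_level"] = int(quiet)
        ev["nadir"] = int(span.min())
        ev["area_pct_s"] = float(deficit.sum())

    true_mean = float(spo2.mean())

    # --- heart rate ----------------------------------------------------------
    hr_base = _interp(config.hr_anchors, altitude_m) + participant_hr_offset
    if ams_positive:
        hr_base += ge.hr_offset
    hr = np.clip(
        np.floor(hr_base + _ar1(rng, n, 2.0, config.ar_coefficient) + 0.5), 35, 180
    ).astype(np.int64)

    # --- sensor artefacts ----------------------------------------------------
    art_idx = np.flatnonzero(rng.random(n) < config.artefact_rate)
    for i in art_idx:
        u = rng.random()
        if u < 0.5:
            spo2[i] = 500  # sentinel
        elif u < 0.75:
            spo2[i] = max(31, int(spo2[i] - round(rng.uniform(6, 15))))  # step spike
        else:
            spo2[i] = int(round(rng.uniform(5, 26)))  # sub-30 dip

    session = OximetrySession(
        participant_id=participant_id,
        night_label=night_label,
        altitude_m=altitude_m,
        spo2=spo2,
        hr=hr,
    )
    truth = {
        "participant_id": participant_id,
        "night_label": night_label,
        "altitude_m": altitude_m,
        "ams_positive": bool(ams_positive),
        "planned_mean": float(target_mean),
        "pre_event_baseline": base,
        "true_mean": true_mean,
        "events": truth_events,
        "artefact_indices": art_idx.tolist(),
        "duration_s": n,
    }
    return session, truth


def _solve_diff(value: float, slope: float, x_intercept: float, forward: bool) -> float:
    """Solve diff = slope*(avg - x_int) where avg couples both measures.

    forward=True:  given the *reference*, return diff (ref - derived).
    forward=False: given the *derived-from* quantity, return diff
    (reference - given) so reference = given + diff.
    """
    if forward:
        return slope * (value - x_intercept) / (1.0 + slope / 2.0)
    return slope * (value - x_intercept) / (1.0 - slope / 2.0)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the full expedition dataset.

    One session per participant per profile night, morning and evening Lake
    Louise records, daily morning spot oximetry and capillary SaO2 on the
    configured sampling days.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bias = config.sao2_bias_model
    sessions, lls_records, spots, capillary = [], [], [], []
    truth_nights = []
    truth_participants = {}

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        offset = rng.normal(0.0, config.participant_sd)
        hr_off = rng.normal(0.0, config.participant_hr_sd)
        a = config.susceptibility_coupling
        suscept = a * (-offset / max(config.participant_sd, 1e-9)) + np.sqrt(
            1 - a * a
        ) * rng.standard_normal()
        truth_participants[pid] = {
            "saturation_offset": offset,
            "hr_offset": hr_off,
            "susceptibility": float(suscept),
        }
        for night_label, alt in config.ascent_profile:
            positive = bool(rng.random() < config.ams_fraction)
            session, truth = generate_night(
                config, rng, pid, night_label, alt,
                participant_offset=offset,
                participant_hr_offset=hr_off,
                ams_positive=positive,
            )
            sessions.append(session)
            truth_nights.append(truth)

            alt_scale = max(0.0, (alt - 2000.0) / 1000.0)
            if positive:
                latent = 4.0 + 1.8 * suscept + 0.3 * alt_scale + rng.normal(0, 0.5)
                total = int(np.clip(round(latent), 3, 12))
                headache = int(np.clip(1 + (total - 3) // 3, 1, min(3, total)))
            else:
                latent = 1.1 + 0.9 * suscept + 0.25 * alt_scale + rng.normal(0, 0.35)
                total = int(np.clip(round(latent), 0, 2))
                headache = 1 if (total >= 1 and rng.random() < 0.15) else 0
            lls_records.append(
                LLSRecord(pid, night_label, MORNING, total, headache)
            )
            ev_latent = 0.3 + 0.25 * suscept + 0.3 * alt_scale + rng.normal(0, 0.6)
            ev_total = int(np.clip(round(ev_latent), 0, 12))
            lls_records.append(
                LLSRecord(pid, night_label, EVENING, ev_total,
                          min(ev_total, 1) if rng.random() < 0.2 else 0)
            )

            # morning physiology: capillary SaO2 derived from the realized
            # overnight mean through the overnight difference line, spot
            # SpO2 from SaO2 through the morning difference line.
            o_true = truth["true_mean"]
            sao2 = o_true + _solve_diff(o_true, bias.ov_slope, bias.ov_x_intercept, forward=False)
            sao2 = float(np.clip(sao2 + rng.normal(0, bias.sao2_noise_sd), 40.0, 100.0))
            mo_mean = sao2 - _solve_diff(sao2, bias.mo_slope, bias.mo_x_intercept, forward=True)
            # display averaging over a ~75 s window of integer readings
            window = np.floor(mo_mean + rng.normal(0, bias.spot_noise_sd, config.spot_window_s) + 0.5)
            spot_val = float(np.clip(window.mean(), 1.0, 100.0))
            spots.append(SpotMeasurement(pid, night_label, round(spot_val, 1)))
            if night_label in config.capillary_days:
                capillary.append(CapillarySample(pid, night_label, round(sao2, 1)))

    ground_truth = {"participants": truth_participants, "nights": truth_nights}
    return Cohort(sessions, lls_records, spots, capillary, ground_truth, config)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort in the on-disk session/table formats plus ground truth."""
    out = Path(out_dir)
    sess_dir = out / "sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for s in cohort.sessions:
        fname = f"{s.participant_id}_{s.night_label}.csv"
        write_session(s, sess_dir / fname)
        index.append(
            {
                "file": f"sessions/{fname}",
                "participant_id": s.participant_id,
                "night_label": s.night_label,
                "altitude_m": s.altitude_m,
            }
        )
    write_lls_table(cohort.lls_records, out / "lls.csv")
    write_spot_table(cohort.spots, out / "spots.csv")
    write_capillary_table(cohort.capillary, out / "capillary.csv")
    with open(out / "sessions_index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)
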