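"""Synthetic cohort generator: determinism, calibration and structure."""

import numpy as np
import pytest

from noctox.artefacts import clean_series, flag_artefacts
from noctox.distribution import build_distribution
from noctox.errors import ConfigError
from noctox.events import detect_desaturations
from noctox.session import MORNING
from noctox.simulate import (
    CohortConfig,
    EventModel,
    generate_cohort,
    generate_night,
)
from noctox.stats import classify_ams


def small_config(**kw):
    """Scaled-down cohort for fast structural tests."""
    defaults = dict(
        n_participants=3,
        ascent_profile=(("day2", 1400), ("day3", 3300), ("day4", 4800)),
        night_duration_s=3600,
        night_duration_sd_s=0.0,
        min_night_duration_s=3600,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_dataset(self):
        a = generate_cohort(small_config(), seed=42)
        b = generate_cohort(small_config(), seed=42)
        for sa, sb in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(sa.spo2, sb.spo2)
            np.testing.assert_array_equal(sa.hr, sb.hr)
        assert a.lls_records == b.lls_records
        assert a.spots == b.spots
        assert a.capillary == b.capillary

    def test_different_seed_differs(self):
        a = generate_cohort(small_config(), seed=1)
        b = generate_cohort(small_config(), seed=2)
        assert any(
            not np.array_equal(sa.spo2, sb.spo2)
            for sa, sb in zip(a.sessions, b.sessions)
        )


class TestStructure:
    def test_counts(self):
        cfg = small_config()
        c = generate_cohort(cfg, seed=0)
        n = cfg.n_participants * len(cfg.ascent_profile)
        assert len(c.sessions) == n
        assert len(c.spots) == n
        morning = [r for r in c.lls_records if r.time_of_day == MORNING]
        assert len(morning) == n
        assert {s.day_label for s in c.capillary} <= set(cfg.capillary_days)

    def test_default_cohort_is_216_nights(self):
        cfg = CohortConfig()
        assert cfg.n_participants * len(cfg.ascent_profile) == 216

    def test_ams_fraction_zero_all_negative(self):
        c = generate_cohort(small_config(ams_fraction=0.0), seed=3)
        for r in c.lls_records:
            if r.time_of_day == MORNING:
                assert not classify_ams(r).is_positive

    def test_lls_consistent_with_truth_labels(self):
        c = generate_cohort(small_config(ams_fraction=0.5), seed=5)
        label = {
            (t["participant_id"], t["night_label"]): t["ams_positive"]
            for t in c.ground_truth["nights"]
        }
        for r in c.lls_records:
            if r.time_of_day == MORNING:
                assert classify_ams(r).is_positive == label[(r.participant_id, r.day_label)]

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            CohortConfig(ascent_profile=()).validate()
        with pytest.raises(ConfigError):
            CohortConfig(ascent_profile=(("day2", -5),)).validate()
        with pytest.raises(ConfigError):
            CohortConfig(ams_fraction=1.5).validate()


class TestSignalModel:
    def test_degenerate_config_constant_trace(self, rng):
        cfg = CohortConfig(
            noise_sd=0.0, artefact_rate=0.0,
            event_model=EventModel(rate_anchors={0: 0.0, 9000: 0.0}),
        )
        s, truth = generate_night(cfg, rng, "P01", "day2", 140, duration_s=1200)
        assert np.unique(s.spo2).size == 1
        assert s.spo2[0] == 97  # sea-level anchor
        assert truth["events"] == []

    def test_detector_recovers_injected_events_on_clean_signal(self):
        cfg = CohortConfig(
            noise_sd=0.0, artefact_rate=0.0,
            event_model=EventModel(ramp_s=0, min_separation_s=60),
        )
        rng = np.random.default_rng(11)
        for _ in range(5):
            s, truth = generate_night(cfg, rng, "P", "n", 4800, duration_s=7200)
            cs = clean_series(s)
            events = detect_desaturations(cs)
            assert len(events) == len(truth["events"])
            assert sum(e.area_pct_s for e in events) == pytest.approx(
                sum(t["area_pct_s"] for t in truth["events"])
            )

    def test_injected_artefact_fraction_recovered_exactly_without_events(self):
        cfg = CohortConfig(
            noise_sd=0.5, artefact_rate=0.0075,
            event_model=EventModel(rate_anchors={0: 0.0, 9000: 0.0}),
        )
        rng = np.random.default_rng(4)
        total_injected = total_flagged = total_n = 0
        for _ in range(20):
            s, truth = generate_night(cfg, rng, "P", "n", 3300, duration_s=7200)
            r = flag_artefacts(s)
            total_injected += len(truth["artefact_indices"])
            total_flagged += r.flagged_indices.size
            total_n += len(s)
        assert total_flagged == total_injected
        assert 100.0 * total_flagged / total_n == pytest.approx(0.75, abs=0.25)

    def test_cohort_mean_artefact_index_near_injection_rate(self):
        # includes events, where steep falls can cascade a few extra flags
        cfg = CohortConfig()
        rng = np.random.default_rng(8)
        ais = []
        for i in range(100):
            alt = [140, 3300, 3850, 4800][i % 4]
            s, _ = generate_night(cfg, rng, "P", "n", alt, duration_s=7200)
            ais.append(flag_artefacts(s).artefact_index_pct)
        assert np.mean(ais) == pytest.approx(0.75, abs=0.2)

    def test_group_offset_calibration(self):
        # flat profile and balanced groups isolate the configured offset
        cfg = CohortConfig(
            n_participants=14,
            ascent_profile=tuple((f"day{i}", 3300) for i in range(2, 14)),
            ams_fraction=0.5,
            night_duration_s=7200,
            night_duration_sd_s=0.0,
            min_night_duration_s=7200,
        )
        c = generate_cohort(cfg, seed=21)
        label = {
            (t["participant_id"], t["night_label"]): t["ams_positive"]
            for t in c.ground_truth["nights"]
        }
        pos, neg = [], []
        for s in c.sessions:
            flag_artefacts(s)
            m = float(s.spo2[s.valid_mask].mean())
            (pos if label[s.key] else neg).append(m)
        contrast = np.mean(pos) - np.mean(neg)
        assert contrast == pytest.approx(-5.0, abs=0.5)

    def test_top_camp_flattens_distribution(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(13)
        k_low, k_top = [], []
        for _ in range(30):
            for alt, out in ((140, k_low), (4800, k_top)):
                s, _ = generate_night(cfg, rng, "P", "n", alt, duration_s=7200)
                flag_artefacts(s)
                d = build_distribution(clean_series(s))
                out.append(d.kurtosis_proper)
        assert np.median(k_top) < np.median(k_low)

    def test_ground_truth_round_trips_planned_means(self):
        cfg = small_config(noise_sd=0.5)
        c = generate_cohort(cfg, seed=9)
        for t in c.ground_truth["nights"]:
            # realized clean mean tracks the planned observed mean
            assert abs(t["true_mean"] - t["planned_mean"]) < 2.0
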