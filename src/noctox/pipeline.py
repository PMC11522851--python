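"""End-to-end pipeline: simulate or ingest -> clean -> events -> distribution
-> features -> group comparison / ROC / agreement / correlations -> report.

The pipeline is deterministic given the seed and inputs.  Per-night
failures are logged and surface as not-assessable markers in the feature
table; they are never silently dropped.  A run manifest records the
configuration, seed and every excluded night.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artefacts import clean_series, flag_artefacts
from .config import (
    ArtefactRules,
    DesaturationConfig,
    DistributionConfig,
    StatsConfig,
    config_to_dict,
)
from .distribution import build_distribution
from .errors import ConfigError, DegenerateGroupingError, NoctoxError
from .events import detect_desaturations, summarize_events
from .features import assemble_features
from .session import (
    MORNING,
    read_capillary_table,
    read_lls_table,
    read_session,
    read_spot_table,
)
from .simulate import Cohort, CohortConfig, generate_cohort
from .stats import (
    bland_altman,
    classify_ams,
    compare_groups,
    exploratory_correlations,
    roc_youden,
)

log = logging.getLogger(__name__)

#: feature columns compared between AMS subgroups and fed to ROC analysis.
COMPARISON_METRICS = (
    "mo_spo2",
    "ov_spo2_mean",
    "hr_mean",
    "hr_over_spo2",
    "delta_spo2",
    "variance",
    "total_desaturations",
    "mean_event_duration_s",
    "odi_per_h",
    "hypoxic_burden",
    "tst80_pct",
)

#: features correlated against LLS_peak in the exploratory table.
CORRELATION_FEATURES = (
    "mo_spo2",
    "ov_spo2_mean",
    "lowest_ma_3600s",
    "lowest_ma_900s",
    "first15_mean",
    "last15_mean",
)


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None
    artefact_rules: ArtefactRules = field(default_factory=ArtefactRules)
    desaturation: DesaturationConfig = field(default_factory=DesaturationConfig)
    distribution: DistributionConfig = field(default_factory=DistributionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate and not self.input_dir:
            raise ConfigError("either simulate=True or input_dir must be given")
        self.cohort.validate()
        self.artefact_rules.validate()
        self.desaturation.validate()
        self.distribution.validate()
        self.stats.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            c = dict(kwargs["cohort"])
            for key, sub in (
                ("group_effects", "GroupEffects"),
                ("event_model", "EventModel"),
                ("sao2_bias_model", "SaO2BiasModel"),
            ):
                if key in c and isinstance(c[key], dict):
                    from . import simulate as _sim
                    c[key] = getattr(_sim, sub)(**c[key])
            # serialized anchor maps come back with string keys; ranges as lists
            for key in ("saturation_anchors", "hr_anchors"):
                if key in c and isinstance(c[key], dict):
                    c[key] = {int(float(k)): float(v) for k, v in c[key].items()}
            em = c.get("event_model")
            if em is not None and not isinstance(em, dict):
                em.rate_anchors = {
                    int(float(k)): float(v) for k, v in em.rate_anchors.items()
                }
                em.depth_range = tuple(em.depth_range)
                em.duration_range = tuple(em.duration_range)
            if "ascent_profile" in c:
                c["ascent_profile"] = tuple(tuple(x) for x in c["ascent_profile"])
            if "capillary_days" in c:
                c["capillary_days"] = tuple(c["capillary_days"])
            kwargs["cohort"] = CohortConfig(**c)
        for key, klass in (
            ("artefact_rules", ArtefactRules),
            ("desaturation", DesaturationConfig),
            ("distribution", DistributionConfig),
            ("stats", StatsConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    features: pd.DataFrame
    comparisons: pd.DataFrame
    roc: pd.DataFrame
    agreement: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict
    notices: list


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_cohort_from_dir(input_dir, seed: int = 0) -> Cohort:
    """Load a cohort previously written by the ``simulate`` stage."""
    root = Path(input_dir)
    with open(root / "sessions_index.json") as fh:
        index = json.load(fh)
    sessions = [
        read_session(
            root / e["file"], e["participant_id"], e["night_label"], e["altitude_m"]
        )
        for e in index
    ]
    gt_path = root / "ground_truth.json"
    truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return Cohort(
        sessions=sessions,
        lls_records=read_lls_table(root / "lls.csv"),
        spots=read_spot_table(root / "spots.csv"),
        capillary=read_capillary_table(root / "capillary.csv"),
        ground_truth=truth,
        config=CohortConfig(seed=seed),
    )


def night_features_table(cohort: Cohort, config: PipelineConfig) -> tuple[pd.DataFrame, list]:
    """Run clean -> events -> distribution -> features for every session."""
    rows, notices = [], []
    spot_map = {(s.participant_id, s.day_label): s.mo_spo2 for s in cohort.spots}
    for session in cohort.sessions:
        key = session.key
        try:
            report = flag_artefacts(session, config.artefact_rules)
            clean = clean_series(session)
            events = detect_desaturations(clean, config.desaturation)
            summary = summarize_events(events, report.clean_duration_s)
            dist = build_distribution(clean, config.distribution)
            feats = assemble_features(session, report, clean, summary, dist)
            row = feats.to_row()
        except NoctoxError as exc:
            notices.append({"stage": "features", "session": key, "event": str(exc)})
            log.warning("stage=features session=%s event=%s", key, exc)
            row = {
                "participant_id": session.participant_id,
                "night_label": session.night_label,
                "altitude_m": session.altitude_m,
            }
        row["mo_spo2"] = spot_map.get(key, np.nan)
        rows.append(row)
    return pd.DataFrame(rows), notices


def _ams_by_night(cohort: Cohort) -> dict[tuple[str, str], bool]:
    status = {}
    for rec in cohort.lls_records:
        if rec.time_of_day == MORNING:
            st = classify_ams(rec)
            status[(st.participant_id, st.day_label)] = st.is_positive
    return status


def comparison_tables(
    features: pd.DataFrame,
    cohort: Cohort,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Table-1 analog (Mann-Whitney + Hodges-Lehmann) and Table-2 analog (ROC)."""
    ams = _ams_by_night(cohort)
    labels = features.apply(
        lambda r: ams.get((r["participant_id"], r["night_label"])), axis=1
    )
    comp_rows, roc_rows, notices = [], [], []
    for metric in COMPARISON_METRICS:
        if metric not in features.columns:
            continue
        vals = features[metric]
        mask = vals.notna() & labels.notna()
        pos = vals[mask & (labels == True)].to_numpy(float)  # noqa: E712
        neg = vals[mask & (labels == False)].to_numpy(float)  # noqa: E712
        pooled = np.concatenate([pos, neg])
        if pooled.size >= 3 and pooled.std(ddof=1) > 0:
            # +-k SD outliers judged against the pooled feature distribution
            k = config.stats.outlier_k
            mu, sd = pooled.mean(), pooled.std(ddof=1)
            pos = pos[np.abs(pos - mu) <= k * sd]
            neg = neg[np.abs(neg - mu) <= k * sd]
        try:
            gc = compare_groups(pos, neg, metric)
            comp_rows.append(
                {
                    "metric": metric,
                    "median_pos": gc.median_pos,
                    "iqr25_pos": gc.iqr_pos[0],
                    "iqr75_pos": gc.iqr_pos[1],
                    "median_neg": gc.median_neg,
                    "iqr25_neg": gc.iqr_neg[0],
                    "iqr75_neg": gc.iqr_neg[1],
                    "hl_difference": gc.hl_median_difference,
                    "ci95_lo": gc.ci95[0],
                    "ci95_hi": gc.ci95[1],
                    "p_value": gc.p_value,
                    "n_pos": gc.n_pos,
                    "n_neg": gc.n_neg,
                }
            )
            roc = roc_youden(pos, neg, metric, config.stats)
            roc_rows.append(
                {
                    "metric": metric,
                    "auc": roc.auc,
                    "auc_ci_lo": roc.auc_ci95[0],
                    "auc_ci_hi": roc.auc_ci95[1],
                    "p_value": roc.p_value,
                    "cutoff": roc.cutoff_value,
                    "direction": roc.cutoff_direction,
                    "sensitivity_pct": 100 * roc.sensitivity,
                    "specificity_pct": 100 * roc.specificity,
                    "youden_reported": roc.youden_reported,
                    "youden_standard": roc.youden_standard,
                }
            )
        except DegenerateGroupingError as exc:
            notices.append({"stage": "compare", "metric": metric, "event": str(exc)})
            log.warning("stage=compare metric=%s event=%s", metric, exc)
    return pd.DataFrame(comp_rows), pd.DataFrame(roc_rows), notices


def agreement_table(features: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Bland-Altman analogs: SaO2 vs mo-SpO2, SaO2 vs ov-SpO2, ov vs mo."""
    spot = {(s.participant_id, s.day_label): s.mo_spo2 for s in cohort.spots}
    ov = {
        (r.participant_id, r.night_label): r.ov_spo2_mean
        for r in features.itertuples()
        if pd.notna(getattr(r, "ov_spo2_mean", np.nan))
    }
    rows = []
    pairs_mo, pairs_ov, pairs_cross = [], [], []
    for cap in cohort.capillary:
        key = (cap.participant_id, cap.day_label)
        if key in spot:
            pairs_mo.append((cap.sao2, spot[key]))
        if key in ov:
            pairs_ov.append((cap.sao2, ov[key]))
        if key in spot and key in ov:
            pairs_cross.append((ov[key], spot[key]))
    for name, pairs in (
        ("sao2_vs_mo_spo2", pairs_mo),
        ("sao2_vs_ov_spo2", pairs_ov),
        ("ov_vs_mo_spo2", pairs_cross),
    ):
        if len(pairs) < 3:
            rows.append({"comparison": name, "n_pairs": len(pairs)})
            continue
        ref, tst = np.array(pairs).T
        ba = bland_altman(ref, tst)
        rows.append(
            {
                "comparison": name,
                "n_pairs": ba.n_pairs,
                "bias": ba.bias,
                "sd_diff": ba.sd_diff,
                "loa_lo": ba.loa95[0],
                "loa_hi": ba.loa95[1],
                "slope": ba.slope,
                "slope_ci_lo": ba.slope_ci[0] if ba.slope_ci else np.nan,
                "slope_ci_hi": ba.slope_ci[1] if ba.slope_ci else np.nan,
                "x_intercept": ba.x_intercept,
                "r_squared": ba.r_squared,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(features: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Table-3 analog: features from late-ascent nights vs LLS_peak."""
    altitudes = dict(cohort.config.ascent_profile) if cohort.config else {}
    nights = [n for n, _ in cohort.config.ascent_profile] if cohort.config else []
    # the last night at each pre-summit altitude plus the first summit night
    wanted = [n for n in nights if altitudes.get(n, 0) >= 3000][:: 1]
    if not wanted:
        wanted = sorted(features["night_label"].unique())
    cols = [c for c in CORRELATION_FEATURES if c in features.columns]
    return exploratory_correlations(features, cohort.lls_records, cols, wanted)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and return the report bundle."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.simulate:
        cohort = generate_cohort(config.cohort, seed=config.seed)
    else:
        cohort = load_cohort_from_dir(config.input_dir, seed=config.seed)

    features, notices = night_features_table(cohort, config)
    comparisons, roc, comp_notices = comparison_tables(features, cohort, config)
    notices.extend(comp_notices)
    agreement = agreement_table(features, cohort)
    correlations = correlation_table(features, cohort)

    cfg_dict = _jsonable(config.to_dict())
    manifest = {
        "noctox_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_sessions": len(cohort.sessions),
        "n_feature_rows": len(features),
        "excluded": [n for n in notices if n.get("stage") == "features"],
    }
    result = PipelineResult(
        features, comparisons, roc, agreement, correlations, manifest, notices
    )
    if config.out_dir:
        write_report(result, config.out_dir)
    return result


def write_report(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "night_features.csv", index=False)
    result.comparisons.to_csv(out / "group_comparison.csv", index=False)
    result.roc.to_csv(out / "roc.csv", index=False)
    result.agreement.to_csv(out / "agreement.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(result.manifest), fh, indent=1)
    bundle = {
        "comparisons": result.comparisons.to_dict(orient="records"),
        "roc": result.roc.to_dict(orient="records"),
        "agreement": result.agreement.to_dict(orient="records"),
        "correlations": result.correlations.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=1)
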