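"""Tunable thresholds for the signal-processing and statistics stages.

Every threshold the pipeline applies lives here with its default; the
defaults are the values used throughout the documentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError


@dataclass
class ArtefactRules:
    """The three artefact-rejection criteria for 1 Hz SpO2 traces.

    A sample is an artefact when its SpO2 is below ``min_spo2`` (rule 1),
    above ``max_spo2`` (rule 2, catches device sentinels such as 500), or
    deviates by more than ``max_step`` percentage points from the most
    recent *retained* sample (rule 3).
    """

    min_spo2: float = 30.0
    max_spo2: float = 100.0
    max_step: float = 4.0

    def validate(self) -> None:
        if not (0 <= self.min_spo2 < self.max_spo2):
            raise ConfigError("require 0 <= min_spo2 < max_spo2")
        if self.max_step <= 0:
            raise ConfigError("max_step must be positive")


@dataclass
class DesaturationConfig:
    """Desaturation-event scoring parameters.

    drop_pct
        Minimum fall below the rolling baseline (max SpO2 over the
        preceding ``baseline_window_s`` of clean signal) to open an event.
    recovery_delta_pct
        Hysteresis: an event closes once SpO2 recovers to within this many
        points of the onset baseline.
    min_duration_s
        Events shorter than this are discarded.
    max_gap_s
        Events and baseline windows never span clean-data gaps longer
        than this many seconds.
    """

    drop_pct: float = 4.0
    baseline_window_s: int = 20
    recovery_delta_pct: float = 2.0
    min_duration_s: int = 10
    max_gap_s: int = 5

    def validate(self) -> None:
        if self.drop_pct <= 0 or self.recovery_delta_pct < 0:
            raise ConfigError("drop_pct must be > 0 and recovery_delta_pct >= 0")
        if self.recovery_delta_pct > self.drop_pct:
            raise ConfigError("recovery_delta_pct must not exceed drop_pct")
        if self.baseline_window_s < 1 or self.min_duration_s < 1 or self.max_gap_s < 0:
            raise ConfigError("window/duration/gap parameters must be positive")


@dataclass
class DistributionConfig:
    """Integer-bin SpO2 frequency distribution options."""

    bin_min: int = 30
    bin_max: int = 100
    #: variance denominator: 1 -> sample variance (n-1), 0 -> population.
    ddof: int = 1
    #: if True, time-below thresholds are inclusive ("at or below").
    inclusive_tst: bool = False
    kurtosis_flag_threshold: float = 7.0
    skew_flag_threshold: float = 2.0

    def validate(self) -> None:
        if self.bin_min >= self.bin_max:
            raise ConfigError("bin_min must be below bin_max")
        if self.ddof not in (0, 1):
            raise ConfigError("ddof must be 0 or 1")


@dataclass
class StatsConfig:
    """Diagnostic-statistics layer options."""

    outlier_k: float = 3.0
    #: AUC confidence-interval method; only "hanley-mcneil" is implemented.
    auc_ci_method: str = "hanley-mcneil"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.outlier_k <= 0:
            raise ConfigError("outlier_k must be positive")
        if self.auc_ci_method != "hanley-mcneil":
            raise ConfigError(f"unknown AUC CI method {self.auc_ci_method!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


#: moving-average window lengths (seconds) extracted per night: 30 s, 3 min,
#: 15 min and 60 min.
MA_WINDOWS_S: tuple[int, ...] = (30, 180, 900, 3600)

#: first/last edge-window length (seconds).
EDGE_WINDOW_S: int = 900


def config_to_dict(cfg) -> dict:
    """Flatten any of the config dataclasses to a plain dict (for manifests)."""
    return asdict(cfg)
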