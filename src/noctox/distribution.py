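"""Relative/cumulative SpO2 frequency distributions and their moments.

Clean samples are assigned to integer SpO2 bins spanning 30-100% (the
post-filtering device range); moments (mean, variance, skewness and
kurtosis proper) are computed on the raw clean samples, not the histogram,
to avoid binning bias.  Kurtosis proper is the non-excess fourth
standardized moment (normal distribution = 3).  High kurtosis marks a
"peaked" saturation distribution — most of the night spent at a few
saturations — while ascent to altitude flattens the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .artefacts import CleanSeries
from .config import DistributionConfig
from .errors import DegenerateRecordingError, InputDomainError, InsufficientDataError


@dataclass
class SaturationDistribution:
    """Integer-bin SpO2 distribution with moments of the underlying samples."""

    bin_edges: np.ndarray  # integer SpO2 values, bin_min..bin_max
    rel_freq: np.ndarray   # proportion of clean samples per bin (sums to 1)
    cum_freq: np.ndarray   # proportion at or below each bin (ends at 1)
    n_samples: int
    mean: float
    variance: float
    skewness: float | None      # None when variance is zero (undefined)
    kurtosis_proper: float | None
    inclusive_tst: bool = False

    @property
    def moments_defined(self) -> bool:
        return self.skewness is not None


@dataclass
class ShapeFlags:
    """Threshold flags on the distribution's higher moments."""

    kurtosis_significant: bool | None  # kurtosis proper > 7
    substantial_asymmetry: bool | None  # |skewness| >= 2
    skew_direction: str | None  # "positive" | "negative" | "zero"
    assessable: bool = True


def _values(data) -> np.ndarray:
    if isinstance(data, CleanSeries):
        return data.spo2
    return np.asarray(data, dtype=np.float64)


def build_distribution(
    data, cfg: DistributionConfig | None = None
) -> SaturationDistribution:
    """Build the binned distribution and moments from a clean series.

    Non-integer samples are rounded half-up to their integer bin; moments
    use the raw (unrounded) samples.  Requires at least two samples.
    """
    cfg = cfg or DistributionConfig()
    cfg.validate()
    vals = _values(data)
    n = vals.size
    if n < 2:
        raise InsufficientDataError("need at least 2 clean samples for a distribution")
    bins = np.arange(cfg.bin_min, cfg.bin_max + 1)
    rounded = np.floor(vals + 0.5).astype(np.int64)  # half-up
    if rounded.min() < cfg.bin_min or rounded.max() > cfg.bin_max:
        raise InputDomainError(
            f"samples outside bin range {cfg.bin_min}-{cfg.bin_max}; "
            "run the artefact filter first"
        )
    counts = np.bincount(rounded - cfg.bin_min, minlength=bins.size).astype(np.float64)
    rel = counts / n
    cum = np.cumsum(rel)
    mean = float(vals.mean())
    variance = float(vals.var(ddof=cfg.ddof))
    if np.all(vals == vals[0]):
        skew = kurt = None
    else:
        # unadjusted moment coefficients (no small-sample bias correction):
        # overnight n is large enough that the correction is negligible.
        skew = float(sps.skew(vals, bias=True))
        kurt = float(sps.kurtosis(vals, fisher=False, bias=True))
    return SaturationDistribution(
        bin_edges=bins,
        rel_freq=rel,
        cum_freq=cum,
        n_samples=n,
        mean=mean,
        variance=variance,
        skewness=skew,
        kurtosis_proper=kurt,
        inclusive_tst=cfg.inclusive_tst,
    )


def time_below(data, threshold: float, inclusive: bool | None = None) -> float:
    """Percentage of clean time with SpO2 below (or at-or-below) ``threshold``.

    ``data`` may be a :class:`SaturationDistribution`, a
    :class:`~noctox.artefacts.CleanSeries` or a plain array.  The default
    comparison is strict ("TST of <80% SpO2"); pass ``inclusive=True`` for
    the at-or-below convention.
    """
    if not 30 <= threshold <= 100:
        raise InputDomainError("threshold must lie in 30..100 %SpO2")
    if isinstance(data, SaturationDistribution):
        if inclusive is None:
            inclusive = data.inclusive_tst
        t = int(threshold)
        lo = int(data.bin_edges[0])
        edge = t if inclusive else t - 1
        if edge < lo:
            return 0.0
        edge = min(edge, int(data.bin_edges[-1]))
        return 100.0 * float(data.cum_freq[edge - lo])
    vals = _values(data)
    if vals.size == 0:
        raise DegenerateRecordingError("empty clean series")
    if inclusive is None:
        inclusive = False
    hits = (vals <= threshold) if inclusive else (vals < threshold)
    return 100.0 * float(np.count_nonzero(hits)) / vals.size


def flag_distribution_shape(
    dist: SaturationDistribution, cfg: DistributionConfig | None = None
) -> ShapeFlags:
    """Apply the kurtosis-proper > 7 and |skew| >= 2 shape flags."""
    cfg = cfg or DistributionConfig()
    if not dist.moments_defined:
        return ShapeFlags(None, None, None, assessable=False)
    skew = dist.skewness
    direction = "zero" if skew == 0 else ("positive" if skew > 0 else "negative")
    return ShapeFlags(
        kurtosis_significant=dist.kurtosis_proper > cfg.kurtosis_flag_threshold,
        substantial_asymmetry=abs(skew) >= cfg.skew_flag_threshold,
        skew_direction=direction,
    )
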