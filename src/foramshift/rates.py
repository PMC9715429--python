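"""Identity-aware biodiversity change: richness, gains/losses, rates.

For each site the oldest (glacial) sample is the baseline.  Every
younger sample is compared to it, taking species identity into account:
gains are species present now but absent in the baseline, losses the
reverse, both normalized by the pooled species set of the pair.  Rates
of change are ordinary least-squares slopes of richness, gains and
losses against time-towards-the-present, so a positive rate means an
increase through time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError, ValidationError
from .samples import AssemblageSample, SiteSeries

#: a taxon is present iff its abundance is strictly greater than this
DEFAULT_PRESENCE_THRESHOLD = 0.0


def richness(sample: AssemblageSample, threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> int:
    """Number of taxa with abundance strictly above ``threshold``.

    The default threshold of 0 means a single counted individual counts
    as present; ``threshold`` (a proportion) supports sensitivity
    analyses with a minimum-detection cutoff.
    """
    return int(np.count_nonzero(sample.abundance > threshold))


@dataclass(frozen=True)
class GainsLosses:
    """Identity-aware turnover of one sample against the baseline."""

    age: float
    gains: float
    losses: float
    union_size: int

    def __post_init__(self) -> None:
        if self.gains + self.losses > 1 + 1e-12:
            raise ValidationError("gains + losses cannot exceed 1")


def gains_losses(
    sample: AssemblageSample,
    baseline: AssemblageSample,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> GainsLosses:
    """Proportions of species gained and lost relative to the baseline.

    gains  = |present in sample, absent in baseline| / |union|
    losses = |absent in sample, present in baseline| / |union|

    where the union pools the species observed in either sample.  The
    exact identity ``richness(sample) − richness(baseline) =
    (gains − losses) × union_size`` holds in integer arithmetic.
    """
    a = sample.abundance > threshold
    b = baseline.abundance > threshold
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise DegenerateSampleError("both samples are empty; turnover undefined")
    gained = int(np.count_nonzero(a & ~b))
    lost = int(np.count_nonzero(~a & b))
    return GainsLosses(
        age=sample.age, gains=gained / union, losses=lost / union, union_size=union
    )


def rate_slope(values, ages) -> float:
    """OLS slope of ``values`` against time-towards-present (−age).

    Positive slope = increase towards the present, in value units per kyr.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages):
        raise ValidationError("values and ages must have equal length")
    if len(values) < 3:
        raise InsufficientDataError(f"need >= 3 points for a rate, got {len(values)}")
    return float(np.polyfit(-ages, values, 1)[0])


def rate_slope_with_se(values, ages) -> tuple[float, float]:
    """Slope and its standard error from the same OLS fit."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) < 3:
        raise InsufficientDataError(f"need >= 3 points for a rate, got {len(values)}")
    res = stats.linregress(-ages, values)
    return float(res.slope), float(res.stderr)


@dataclass(frozen=True)
class RatesRecord:
    """Per-site rates of biodiversity change (per kyr)."""

    site_id: str
    latitude: float
    richness_rate: float
    gains_rate: float
    losses_rate: float


def series_turnover(
    series: SiteSeries, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> tuple[np.ndarray, np.ndarray, list[GainsLosses]]:
    """Per-sample richness and gains/losses against the oldest sample.

    Returns (ages, richness values, GainsLosses list), ordered young→old
    like the series itself.  The baseline compared to itself contributes
    gains = losses = 0 at its own age, anchoring the regressions.
    """
    baseline = series.oldest
    ages = series.ages
    rich = np.array([richness(s, threshold) for s in series.samples])
    gl = [gains_losses(s, baseline, threshold) for s in series.samples]
    return ages, rich, gl


def site_rates(series: SiteSeries, threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> RatesRecord:
    """Linear rates of richness, gains and losses over the whole series."""
    if len(series) < 3:
        raise InsufficientDataError(
            f"series {series.site_id!r} has {len(series)} samples; need >= 3"
        )
    ages, rich, gl = series_turnover(series, threshold)
    return RatesRecord(
        site_id=series.site_id,
        latitude=series.latitude,
        richness_rate=rate_slope(rich, ages),
        gains_rate=rate_slope([g.gains for g in gl], ages),
        losses_rate=rate_slope([g.losses for g in gl], ages),
    )


@dataclass(frozen=True)
class RateDensity:
    """Kernel density summary of one rate across sites."""

    grid: np.ndarray
    density: np.ndarray
    mean: float


@dataclass(frozen=True)
class RatesSummary:
    richness: RateDensity
    gains: RateDensity
    losses: RateDensity
    map_latitudes: np.ndarray
    map_records: tuple[RatesRecord, ...]


def _density(values: np.ndarray, n_grid: int = 256) -> RateDensity:
    mean = float(values.mean())
    spread = values.std()
    if spread == 0:
        # all rates identical: degenerate density, a point mass at the value
        grid = np.array([values[0]])
        return RateDensity(grid=grid, density=np.array([np.inf]), mean=mean)
    kde = stats.gaussian_kde(values)  # Scott's rule bandwidth
    pad = 3 * spread
    grid = np.linspace(values.min() - pad, values.max() + pad, n_grid)
    return RateDensity(grid=grid, density=kde(grid), mean=mean)


def rates_summary(records: Sequence[RatesRecord]) -> RatesSummary:
    """Across-site density of each rate plus the per-site latitude map."""
    if len(records) < 2:
        raise InsufficientDataError("need >= 2 sites to summarize rates")
    records = tuple(sorted(records, key=lambda r: r.latitude))
    return RatesSummary(
        richness=_density(np.array([r.richness_rate for r in records])),
        gains=_density(np.array([r.gains_rate for r in records])),
        losses=_density(np.array([r.losses_rate for r in records])),
        map_latitudes=np.array([r.latitude for r in records]),
        map_records=records,
    )
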