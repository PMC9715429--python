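"""Per-site compositional trends and their stacked summary.

Each site's dominant mode of assemblage change is the first principal
component (PC1) of its sample-by-species proportion matrix.  PCA leaves
the sign of an axis arbitrary, so polarities are aligned across sites by
the sign of a linear fit of score against age (convention: scores
increase towards the present).  Aligned trends are interpolated to a
common 0.5 kyr grid restricted to the window covered by all series
(2.5–23 ka, avoiding edge effects), pooled, and summarized by a LOESS
fit with a 95% pointwise band that can be compared against a
temperature forcing curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import CoverageError, InsufficientDataError, ValidationError
from .loess import loess
from .samples import SiteSeries
from .synthetic import ForcingCurve


@dataclass(frozen=True)
class TrendSeries:
    """One site's PC1 scores through time."""

    site_id: str
    ages: np.ndarray
    pc1_scores: np.ndarray
    variance_fraction: float

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.pc1_scores):
            raise ValidationError("ages and scores must have equal length")
        if not 0 <= self.variance_fraction <= 1:
            raise ValidationError("variance fraction must be in [0, 1]")


@dataclass(frozen=True)
class StackedTrend:
    """LOESS summary of all aligned, interpolated trends."""

    grid_ages: np.ndarray
    fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def series_pc1(series: SiteSeries) -> TrendSeries:
    """First principal component of a site's composition matrix.

    Covariance-based PCA on relative abundances (no per-species scaling:
    abundances share a scale).  A constant composition has no trend and
    raises.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"series {series.site_id!r} has {len(series)} samples; need >= 3"
        )
    p = series.proportions_matrix()
    if np.allclose(p, p[0], atol=1e-12):
        raise InsufficientDataError(
            f"series {series.site_id!r} has constant composition (zero variance)"
        )
    pca = PCA(n_components=1)
    scores = pca.fit_transform(p)[:, 0]
    return TrendSeries(
        site_id=series.site_id,
        ages=series.ages,
        pc1_scores=scores,
        variance_fraction=float(pca.explained_variance_ratio_[0]),
    )


def _age_slope(trend: TrendSeries) -> float:
    """OLS slope of score against age (centred closed form, exact zeros)."""
    a = trend.ages - trend.ages.mean()
    s = trend.pc1_scores - trend.pc1_scores.mean()
    return float((a @ s) / (a @ a))


def align_polarity(trends: Sequence[TrendSeries]) -> list[TrendSeries]:
    """Resolve PCA sign indeterminacy across sites.

    Convention: scores decrease with age, i.e. increase towards the
    present.  A trend whose linear slope against age is positive is
    negated; an exactly-zero slope is left as is with a warning.
    """
    out = []
    for trend in trends:
        slope = _age_slope(trend)
        if slope > 0:
            out.append(replace(trend, pc1_scores=-trend.pc1_scores))
        else:
            if slope == 0:
                warnings.warn(
                    f"trend {trend.site_id!r} has zero age slope; polarity left unchanged"
                )
            out.append(trend)
    return out


def trend_grid(step: float = 0.5, window: tuple[float, float] = (2.5, 23.0)) -> np.ndarray:
    return np.round(np.arange(window[0], window[1] + step / 2, step), 9)


def interpolate_trend(
    trend: TrendSeries,
    step: float = 0.5,
    window: tuple[float, float] = (2.5, 23.0),
) -> TrendSeries:
    """Linear interpolation of the scores onto the regular age grid.

    The trend must span the window; no extrapolation is performed.
    """
    lo, hi = window
    a_min, a_max = trend.ages.min(), trend.ages.max()
    if a_min > lo or a_max < hi:
        raise CoverageError(
            f"trend {trend.site_id!r} spans [{a_min:g}, {a_max:g}] ka; "
            f"does not cover the window [{lo:g}, {hi:g}] ka"
        )
    grid = trend_grid(step, window)
    scores = np.interp(grid, trend.ages, trend.pc1_scores)
    return replace(trend, ages=grid, pc1_scores=scores)


def stack_loess(
    trends: Sequence[TrendSeries],
    span: float = 0.75,
    ci: float = 0.95,
) -> StackedTrend:
    """LOESS through all (age, score) points of all trends, with a band.

    Trends are expected on a common grid (see :func:`interpolate_trend`);
    the fit is evaluated on the union of their age grids.  The band is
    the pointwise ``ci`` interval from the smoother's equivalent-kernel
    standard errors under approximate normality.
    """
    if len(trends) < 2:
        raise InsufficientDataError("need at least 2 trends to stack")
    ages = np.concatenate([t.ages for t in trends])
    scores = np.concatenate([t.pc1_scores for t in trends])
    grid = np.unique(ages)
    fit, se = loess(ages, scores, grid, span=span, degree=2)
    z = stats.norm.ppf(0.5 + ci / 2)
    return StackedTrend(grid_ages=grid, fit=fit, ci_low=fit - z * se, ci_high=fit + z * se)


@dataclass(frozen=True)
class ForcingComparison:
    """Stacked trend and forcing on a shared grid, both rescaled to [0, 1]."""

    ages: np.ndarray
    trend_rescaled: np.ndarray
    forcing_rescaled: np.ndarray

    @property
    def mismatch(self) -> np.ndarray:
        """Pointwise difference (trend − forcing) of the rescaled curves."""
        return self.trend_rescaled - self.forcing_rescaled

    @property
    def correlation(self) -> float:
        """Pearson correlation of the two curves over the shared grid."""
        return float(np.corrcoef(self.trend_rescaled, self.forcing_rescaled)[0, 1])


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def compare_to_forcing(stacked: StackedTrend, forcing: ForcingCurve) -> ForcingComparison:
    """Put the stacked trend and the forcing on a common [0, 1] scale."""
    in_range = (stacked.grid_ages >= forcing.ages.min()) & (
        stacked.grid_ages <= forcing.ages.max()
    )
    if not np.any(in_range):
        raise ValidationError("stacked trend and forcing have no overlapping ages")
    ages = stacked.grid_ages[in_range]
    return ForcingComparison(
        ages=ages,
        trend_rescaled=_rescale01(stacked.fit[in_range]),
        forcing_rescaled=_rescale01(forcing.anomaly(ages)),
    )
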