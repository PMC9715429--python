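"""The latitudinal diversity gradient (LDG) through time.

Per-sample diversity is measured as species richness and Shannon
entropy H = −Σ p_i log p_i (natural log, nats) on relative abundances.
Samples are pooled into millennial bins and the gradient of each metric
against latitude is smoothed per millennium with the same LOESS settings
as the trend stack.  Diversity change is mapped as the anomaly of each
sample relative to its own site's glacial (19–23 ka) mean, gridded at
1 kyr × 2.5°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .gridding import GridField, grid_hovmoller
from .loess import loess
from .rates import richness
from .samples import AssemblageSample, SiteSeries, LGM_WINDOW, filter_time_window

_LOG_BASES = {"e": 1.0, "2": np.log(2.0), "10": np.log(10.0)}


def shannon(sample_or_proportions, base: str = "e") -> float:
    """Shannon entropy of a composition (natural log by default).

    Zero abundances contribute nothing (0·log 0 := 0); the value lies in
    [0, log S] with the maximum at a perfectly even assemblage.
    """
    if isinstance(sample_or_proportions, AssemblageSample):
        p = sample_or_proportions.proportions()
    else:
        from .samples import to_relative_abundance

        p = to_relative_abundance(sample_or_proportions)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / _LOG_BASES[base]


@dataclass(frozen=True)
class DiversityRecord:
    """Richness and Shannon diversity of one sample."""

    sample_id: str
    site_id: str
    age: float
    latitude: float
    richness: int
    shannon: float


def diversity_records(samples: Sequence[AssemblageSample]) -> list[DiversityRecord]:
    return [
        DiversityRecord(
            sample_id=s.sample_id,
            site_id=s.site_id,
            age=s.age,
            latitude=s.latitude,
            richness=richness(s),
            shannon=shannon(s),
        )
        for s in samples
    ]


def millennial_bin(samples: Sequence[AssemblageSample]) -> dict[int, list[AssemblageSample]]:
    """Group samples into left-closed millennial bins [k, k+1) kyr."""
    out: dict[int, list[AssemblageSample]] = {}
    for s in samples:
        if s.age < 0:
            raise ValidationError(f"negative age {s.age} for sample {s.sample_id}")
        out.setdefault(int(np.floor(s.age)), []).append(s)
    return out


@dataclass(frozen=True)
class LdgCurve:
    """LOESS of one diversity metric against latitude for one millennium."""

    millennium: int
    latitudes: np.ndarray
    fit: np.ndarray
    n_samples: int


def ldg_curves(
    records: Sequence[DiversityRecord],
    metric: str = "shannon",
    *,
    span: float = 0.75,
    min_points: int = 10,
    n_grid: int = 50,
) -> dict[int, LdgCurve]:
    """Per-millennium latitudinal gradient of ``metric`` ("shannon"/"richness").

    Millennia with fewer than ``min_points`` samples are skipped with a
    warning; an empty millennium is absent from the result, never zero.
    """
    if metric not in ("shannon", "richness"):
        raise ValidationError(f"unknown metric {metric!r}")
    by_bin: dict[int, list[DiversityRecord]] = {}
    for r in records:
        by_bin.setdefault(int(np.floor(r.age)), []).append(r)
    curves: dict[int, LdgCurve] = {}
    for mill, recs in sorted(by_bin.items()):
        if len(recs) < min_points:
            warnings.warn(f"millennium [{mill}, {mill + 1}) ka has only "
                          f"{len(recs)} samples (< {min_points}); skipped")
            continue
        lats = np.array([r.latitude for r in recs])
        vals = np.array([float(getattr(r, metric)) for r in recs])
        grid = np.linspace(lats.min(), lats.max(), n_grid)
        fit, _ = loess(lats, vals, grid, span=span, degree=2)
        curves[mill] = LdgCurve(millennium=mill, latitudes=grid, fit=fit, n_samples=len(recs))
    return curves


@dataclass(frozen=True)
class LgmAnomaly:
    """Per-sample diversity anomalies vs each site's glacial mean."""

    records: tuple[DiversityRecord, ...]
    anomalies: np.ndarray
    site_lgm_mean: Mapping[str, float]
    grid: GridField


def lgm_anomaly(
    series_collection: Sequence[SiteSeries],
    metric: str = "shannon",
    *,
    window: tuple[float, float] = LGM_WINDOW,
    dt: float = 1.0,
    dlat: float = 2.5,
) -> LgmAnomaly:
    """Difference of each sample's metric from its site's LGM-window mean.

    Sites with no sample inside the window cannot be referenced and are
    excluded with a warning.  By construction, the window samples of a
    site average to anomaly zero.
    """
    if metric not in ("shannon", "richness"):
        raise ValidationError(f"unknown metric {metric!r}")
    metric_fn = shannon if metric == "shannon" else richness

    records: list[DiversityRecord] = []
    anomalies: list[float] = []
    site_means: dict[str, float] = {}
    for series in series_collection:
        in_window = filter_time_window(series.samples, *window)
        if not in_window:
            warnings.warn(
                f"site {series.site_id!r} has no sample in {window}; excluded"
            )
            continue
        site_mean = float(np.mean([metric_fn(s) for s in in_window]))
        site_means[series.site_id] = site_mean
        for s, rec in zip(series.samples, diversity_records(series.samples)):
            records.append(rec)
            anomalies.append(float(getattr(rec, metric)) - site_mean)
    if not records:
        raise InsufficientDataError("no site has samples inside the reference window")
    anomalies_arr = np.array(anomalies)
    grid = grid_hovmoller(
        anomalies_arr,
        np.array([r.age for r in records]),
        np.array([r.latitude for r in records]),
        dt=dt,
        dlat=dlat,
    )
    return LgmAnomaly(
        records=tuple(records),
        anomalies=anomalies_arr,
        site_lgm_mean=site_means,
        grid=grid,
    )
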