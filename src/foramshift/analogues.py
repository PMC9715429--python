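"""No-analogue assemblage detection against a glacial reference pool.

Each query sample is compared (Morisita-Horn) to every sample of the
glacial (19–23 ka) reference compilation; the distance to the nearest
analogue measures how novel the assemblage is.  Whether a distance is
*surprisingly* large is judged against a self-referential null: for each
reference sample, the distance to its nearest non-self analogue within
the reference itself, whose upper percentiles (95th/99th, also for 2nd-
and 3rd-nearest ranks) give thresholds for distances that can occur by
chance among coeval assemblages.  A sample whose nearest-analogue
distance is strictly greater than the threshold is flagged no-analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dissimilarity import _mh_cross
from .errors import EmptyReferenceError, ValidationError
from .gridding import GridField, grid_hovmoller
from .samples import AssemblageSample, ReferenceSet


@dataclass(frozen=True)
class AnalogueDistances:
    """k smallest reference distances for one query sample."""

    sample_id: str
    age: float
    latitude: float
    distances: np.ndarray  # ascending, length k

    @property
    def d_nearest(self) -> float:
        return float(self.distances[0])

    @property
    def d_second(self) -> float:
        return float(self.distances[1])

    @property
    def d_third(self) -> float:
        return float(self.distances[2])


def _query_matrix(
    samples: Sequence[AssemblageSample], reference: ReferenceSet
) -> np.ndarray:
    """(n_query, n_reference) M-H distances with self-pairs masked to inf.

    A query that is itself a member of the reference (same site and age)
    must not match itself, otherwise every reference member would have a
    trivial zero-distance analogue.
    """
    if len(reference) == 0:
        raise EmptyReferenceError("reference set is empty")
    p = np.vstack([s.proportions() for s in samples])
    q = reference.proportions_matrix()
    d = _mh_cross(p, q)
    ref_keys = {r.identity_key: j for j, r in enumerate(reference.samples)}
    for i, s in enumerate(samples):
        j = ref_keys.get(s.identity_key)
        if j is not None:
            d[i, j] = np.inf
    return d


def analogue_distances(
    samples: Sequence[AssemblageSample] | AssemblageSample,
    reference: ReferenceSet,
    k: int = 3,
) -> list[AnalogueDistances]:
    """The k smallest non-self M-H distances to the reference, per sample."""
    if isinstance(samples, AssemblageSample):
        samples = [samples]
    n_avail = len(reference)
    if k > n_avail:
        raise ValidationError(f"k={k} exceeds reference size {n_avail}")
    d = _query_matrix(samples, reference)
    if k >= n_avail:  # every column may be needed; a self-match leaves k-1 finite
        if np.any(np.isinf(np.sort(d, axis=1)[:, :k])):
            raise ValidationError(
                f"k={k} exceeds the number of non-self reference samples"
            )
    part = np.sort(np.partition(d, k - 1, axis=1)[:, :k], axis=1)
    return [
        AnalogueDistances(
            sample_id=s.sample_id, age=s.age, latitude=s.latitude, distances=part[i]
        )
        for i, s in enumerate(samples)
    ]


@dataclass(frozen=True)
class NullThresholds:
    """Percentiles of within-reference non-self analogue distances.

    ``values[(percentile, rank)]`` is the threshold for the given
    percentile (e.g. 95, 99) and analogue rank (1 = nearest).
    """

    values: Mapping[tuple[int, int], float]

    def get(self, percentile: int = 99, rank: int = 1) -> float:
        return self.values[(percentile, rank)]


def _within_reference_ranks(reference: ReferenceSet, max_rank: int) -> np.ndarray:
    """(n_reference, max_rank) non-self analogue distances, ascending."""
    if len(reference) < max_rank + 1:
        raise ValidationError(
            f"reference of {len(reference)} samples cannot support rank {max_rank} "
            "non-self analogues"
        )
    d = _query_matrix(list(reference.samples), reference)
    np.fill_diagonal(d, np.inf)  # exclude self by position too (duplicate keys)
    return np.sort(d, axis=1)[:, :max_rank]


def null_thresholds(
    reference: ReferenceSet,
    percentiles: Sequence[int] = (95, 99),
    ranks: Sequence[int] = (1, 2, 3),
) -> NullThresholds:
    """Self-referential null distances and their upper percentiles.

    Percentiles use linear interpolation between order statistics.
    Thresholds are non-decreasing in both rank and percentile.
    """
    ranked = _within_reference_ranks(reference, max(ranks))
    values = {}
    for r in ranks:
        col = ranked[:, r - 1]
        for p in percentiles:
            values[(int(p), int(r))] = float(np.percentile(col, p))
    return NullThresholds(values=values)


@dataclass(frozen=True)
class Classification:
    """Per-sample novelty flags plus the gridded view."""

    distances: tuple[AnalogueDistances, ...]
    flags: np.ndarray
    threshold: float
    grid_distance: GridField
    grid_flag: GridField


def classify(
    samples: Sequence[AssemblageSample],
    reference: ReferenceSet,
    threshold: float,
    *,
    dt: float = 1.0,
    dlat: float = 2.5,
    cell_statistic: str = "mean",
) -> Classification:
    """Flag samples whose nearest-analogue distance exceeds the threshold.

    The comparison is strict (> threshold).  Nearest distances are also
    gridded at ``dt`` × ``dlat``; the cell flag compares the cell's
    ``cell_statistic`` ("mean", default, or "min") of nearest distances
    to the same threshold.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    dists = analogue_distances(list(samples), reference, k=min(3, len(reference)))
    d_near = np.array([d.d_nearest for d in dists])
    flags = d_near > threshold
    agg = {"mean": np.mean, "min": np.min}[cell_statistic]
    ages = np.array([d.age for d in dists])
    lats = np.array([d.latitude for d in dists])
    grid_d = grid_hovmoller(d_near, ages, lats, dt=dt, dlat=dlat, aggregator=agg)
    grid_f = GridField(
        time_edges=grid_d.time_edges,
        lat_edges=grid_d.lat_edges,
        values=np.where(np.isnan(grid_d.values), np.nan, (grid_d.values > threshold).astype(float)),
        counts=grid_d.counts,
    )
    return Classification(
        distances=tuple(dists),
        flags=flags,
        threshold=threshold,
        grid_distance=grid_d,
        grid_flag=grid_f,
    )


def false_positive_audit(reference: ReferenceSet, percentile: int = 99, rank: int = 1) -> float:
    """Fraction of reference samples flagged against their own threshold.

    Leave-self-out classification of the reference against the
    ``percentile`` threshold of rank-``rank`` non-self distances; by
    construction of the percentile this is at most (100 − percentile)%
    plus one sample's worth.
    """
    ranked = _within_reference_ranks(reference, rank)
    col = ranked[:, rank - 1]
    threshold = float(np.percentile(col, percentile))
    return float(np.mean(col > threshold))
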