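"""Core containers: census samples, site time series, analogue references.

Ages are calibrated kyr BP throughout (0 ka = 1950 CE), latitudes in
degrees north, abundances either raw counts or proportions on the shared
taxonomy layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateSampleError, EmptyReferenceError, ValidationError
from .taxonomy import Taxonomy

#: ages closer than this (kyr) count as the same sample for deduplication
AGE_DEDUP_TOL = 1e-6

#: the glacial reference window (kyr BP) used throughout
LGM_WINDOW = (19.0, 23.0)


def to_relative_abundance(abundance) -> np.ndarray:
    """Normalize an abundance vector to proportions summing to 1.

    Zero entries are preserved; an all-zero vector has no composition and
    raises :class:`DegenerateSampleError`.
    """
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0):
        raise ValidationError("negative abundance")
    total = a.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero abundance vector")
    return a / total


@dataclass(frozen=True)
class AssemblageSample:
    """One census: an abundance vector plus site/age metadata."""

    site_id: str
    latitude: float
    longitude: float
    age: float
    abundance: np.ndarray
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        a = np.asarray(self.abundance, dtype=float)
        if a.ndim != 1 or len(a) != len(self.taxonomy):
            raise ValidationError(
                f"abundance length {a.shape} does not match taxonomy "
                f"({len(self.taxonomy)} taxa)"
            )
        if np.any(a < 0):
            raise ValidationError(
                f"negative abundance in sample {self.site_id!r} @ {self.age} ka"
            )
        object.__setattr__(self, "abundance", a)

    @property
    def sample_id(self) -> str:
        return f"{self.site_id}@{self.age:g}"

    @property
    def identity_key(self) -> tuple[str, float]:
        """Deduplication / self-exclusion key: site id + rounded age."""
        return (self.site_id, round(self.age / AGE_DEDUP_TOL) * AGE_DEDUP_TOL)

    def proportions(self) -> np.ndarray:
        return to_relative_abundance(self.abundance)

    def as_proportions(self) -> "AssemblageSample":
        return replace(self, abundance=self.proportions())


@dataclass(frozen=True)
class SiteSeries:
    """Age-ordered censuses from one site; the unit of trend analysis."""

    site_id: str
    latitude: float
    longitude: float
    samples: tuple[AssemblageSample, ...]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.site_id != self.site_id:
                raise ValidationError(
                    f"sample from site {s.site_id!r} in series {self.site_id!r}"
                )
        ages = self.ages
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise ValidationError(
                f"ages in series {self.site_id!r} must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples])

    def proportions_matrix(self) -> np.ndarray:
        """(n_samples, n_taxa) matrix of relative abundances."""
        return np.vstack([s.proportions() for s in self.samples])

    @property
    def oldest(self) -> AssemblageSample:
        return self.samples[-1]


@dataclass(frozen=True)
class ReferenceSet:
    """Pool of glacial-window samples used as the analogue reference."""

    samples: tuple[AssemblageSample, ...]
    window: tuple[float, float] = LGM_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.window
        for s in self.samples:
            if not (lo <= s.age <= hi):
                raise ValidationError(
                    f"reference sample {s.sample_id} outside window {self.window}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def proportions_matrix(self) -> np.ndarray:
        return np.vstack([s.proportions() for s in self.samples])


def filter_time_window(
    samples: Iterable[AssemblageSample], min_age: float, max_age: float
) -> list[AssemblageSample]:
    """Samples with ``min_age <= age <= max_age`` (closed interval)."""
    if not min_age < max_age:
        raise ValidationError("min_age must be smaller than max_age")
    return [s for s in samples if min_age <= s.age <= max_age]


def group_into_series(samples: Iterable[AssemblageSample]) -> list[SiteSeries]:
    """Group samples by site and sort each site's samples by age."""
    by_site: dict[str, list[AssemblageSample]] = {}
    for s in samples:
        by_site.setdefault(s.site_id, []).append(s)
    series = []
    for site_id, ss in by_site.items():
        ss.sort(key=lambda s: s.age)
        series.append(
            SiteSeries(
                site_id=site_id,
                latitude=ss[0].latitude,
                longitude=ss[0].longitude,
                samples=tuple(ss),
            )
        )
    series.sort(key=lambda sr: sr.site_id)
    return series


def build_reference_set(
    series_collection: Sequence[SiteSeries] = (),
    extra_samples: Iterable[AssemblageSample] = (),
    window: tuple[float, float] = LGM_WINDOW,
) -> ReferenceSet:
    """Union of external glacial samples and in-window series samples.

    Duplicates — the same (site, age) present both in a time series and in
    the external compilation — are kept once, with the external copy
    winning (it is listed first).
    """
    pool: list[AssemblageSample] = list(extra_samples)
    for series in series_collection:
        pool.extend(filter_time_window(series.samples, *window))
    seen: set[tuple[str, float]] = set()
    unique: list[AssemblageSample] = []
    for s in pool:
        if s.identity_key not in seen:
            seen.add(s.identity_key)
            unique.append(s)
    if not unique:
        raise EmptyReferenceError(f"no samples fall in the window {window}")
    return ReferenceSet(samples=tuple(unique), window=window)
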