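"""Synthetic assemblage time series with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: ~25 sites along a 0–65° N transect, each with a census time
series over 0–24 ka at ~0.6 kyr resolution, 41 species whose relative
abundances follow Gaussian thermal response curves, multinomial count
noise at a configurable census depth, a glacial–deglacial–Holocene
temperature forcing, an optional transient mid-latitude cooling
(Heinrich-like) event, and an optional Holocene-only secondary
environmental driver that pushes affected sites towards compositions
with no glacial analogue.

Every run emits a :class:`SyntheticTruth` record (niches, forcing,
per-site temperature histories and expected compositions, secondary-
driver onsets) so recovery tests can score the downstream detectors
against what was actually imposed.

All randomness flows from one integer seed; per-site streams are derived
deterministically from (seed, site_id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DegenerateSampleError, ValidationError
from .samples import AssemblageSample, ReferenceSet, SiteSeries, build_reference_set
from .taxonomy import Taxonomy, default_taxonomy

#: coldest open-ocean sea-surface temperature the generator allows (°C)
SST_FLOOR = -2.0


# ---------------------------------------------------------------------------
# forcing

@dataclass(frozen=True)
class ForcingCurve:
    """Global mean surface temperature anomaly vs age.

    The anomaly is referenced to the 0–2 ka mean (so the late Holocene
    averages to zero) and is glacial-cold before the deglaciation,
    warming monotonically through it, and near-flat after.
    """

    ages: np.ndarray
    gmst_anomaly: np.ndarray

    def anomaly(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages.min() - 1e-9) or np.any(age > self.ages.max() + 1e-9):
            raise ValidationError("age outside the forcing curve's range")
        # ages are stored increasing in kyr BP
        return np.interp(age, self.ages, self.gmst_anomaly)


def make_forcing(
    glacial_anomaly: float = -6.0,
    deglaciation: tuple[float, float] = (11.0, 17.0),
    holocene_anomaly: float = 0.0,
    age_max: float = 24.0,
    age_step: float = 0.1,
) -> ForcingCurve:
    """Piecewise-smooth glacial → Holocene warming curve.

    Cold plateau before ``deglaciation[1]``, a smooth (half-cosine)
    monotone warming ramp across the deglaciation interval, flat
    Holocene, then re-referenced so the 0–2 ka mean is exactly zero.
    """
    t_end, t_start = deglaciation
    if not 0 <= t_end < t_start <= age_max:
        raise ConfigError(f"invalid deglaciation interval {deglaciation}")
    ages = np.round(np.arange(0.0, age_max + age_step / 2, age_step), 9)
    anom = np.empty_like(ages)
    glacial_mask = ages >= t_start
    holocene_mask = ages <= t_end
    ramp_mask = ~glacial_mask & ~holocene_mask
    anom[glacial_mask] = glacial_anomaly
    anom[holocene_mask] = holocene_anomaly
    frac = (ages[ramp_mask] - t_end) / (t_start - t_end)  # 0 at Holocene end
    anom[ramp_mask] = holocene_anomaly + (glacial_anomaly - holocene_anomaly) * (
        1 - np.cos(np.pi * frac)
    ) / 2
    recent = ages <= 2.0
    anom = anom - anom[recent].mean()
    return ForcingCurve(ages=ages, gmst_anomaly=anom)


# ---------------------------------------------------------------------------
# niches and sites

@dataclass(frozen=True)
class SpeciesNiche:
    """Gaussian thermal response curve for one species.

    Relative response at temperature T is
    ``amplitude * exp(-(T - optimum)^2 / (2 tolerance^2))``, optionally
    modulated by ``exp(secondary_sensitivity * secondary)`` where
    ``secondary`` is the dimensionless second environmental axis.
    """

    name: str
    optimum: float
    tolerance: float
    amplitude: float = 1.0
    secondary_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.amplitude <= 0:
            raise ConfigError(f"niche {self.name!r}: tolerance and amplitude must be > 0")


def default_niches(taxonomy: Taxonomy | None = None) -> tuple[SpeciesNiche, ...]:
    """41 niches spanning −2 to 30 °C.

    Optima are evenly spaced; tolerances widen from 3 °C (cold species)
    to 5.5 °C (warm species) so warm waters support more, and more even,
    species — reproducing a latitudinal diversity gradient.  Secondary
    sensitivities are a fixed ±(0.4–1.0) pattern uncorrelated with the
    thermal optimum, so the secondary axis reshuffles abundances instead
    of mimicking a temperature change.
    """
    taxonomy = taxonomy or default_taxonomy()
    n = len(taxonomy)
    optima = np.linspace(-2.0, 30.0, n)
    niches = []
    for i, name in enumerate(taxonomy.species_names):
        tol = 3.0 + 2.5 * (optima[i] - optima[0]) / (optima[-1] - optima[0])
        sens = (-1.0) ** i * (0.4 + 0.6 * ((i * 7) % n) / (n - 1))
        niches.append(
            SpeciesNiche(
                name=name,
                optimum=float(optima[i]),
                tolerance=float(tol),
                amplitude=1.0,
                secondary_sensitivity=float(sens),
            )
        )
    return tuple(niches)


@dataclass(frozen=True)
class HeinrichEvent:
    """Transient local cooling: ``delta_t`` added within [t_start, t_end]."""

    t_start: float = 15.0
    t_end: float = 17.0
    delta_t: float = -4.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ConfigError("Heinrich event needs t_start < t_end")


@dataclass(frozen=True)
class SecondaryDriver:
    """Holocene-only second environmental axis.

    Zero before ``onset`` (kyr BP); afterwards it saturates towards
    ``strength`` with e-folding ``timescale`` kyr:
    ``s(age) = strength * (1 - exp(-(onset - age) / timescale))``.
    """

    onset: float = 11.0
    strength: float = 2.0
    timescale: float = 1.0

    def value(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        out = self.strength * (1.0 - np.exp(-(self.onset - age) / self.timescale))
        return np.where(age < self.onset, out, 0.0)


@dataclass(frozen=True)
class SiteConfig:
    """One site's location, local climate response and sampling design."""

    site_id: str
    latitude: float
    modern_sst: float
    glacial_cooling_scale: float = 1.0
    heinrich_event: HeinrichEvent | None = None
    sampling_ages: tuple[float, ...] = ()
    count_depth: int = 300
    secondary: SecondaryDriver | None = None
    longitude: float = -30.0

    def __post_init__(self) -> None:
        if self.count_depth < 1:
            raise ConfigError("count_depth must be >= 1")


def local_sst(site: SiteConfig, forcing: ForcingCurve, age, *, floor: float = SST_FLOOR):
    """Local sea-surface temperature at ``age``.

    ``modern_sst + glacial_cooling_scale * anomaly(age)``, plus the
    Heinrich offset inside its window, floored at −2 °C (sea water
    freezes; an unbounded linear response would be unphysical at
    high-latitude sites).
    """
    age = np.asarray(age, dtype=float)
    sst = site.modern_sst + site.glacial_cooling_scale * forcing.anomaly(age)
    ev = site.heinrich_event
    if ev is not None:
        sst = sst + np.where((age >= ev.t_start) & (age <= ev.t_end), ev.delta_t, 0.0)
    return np.maximum(sst, floor)


def expected_proportions(
    niches: Sequence[SpeciesNiche], sst: float, secondary: float = 0.0
) -> np.ndarray:
    """Expected relative abundances under the Gaussian niche model."""
    opt = np.array([nc.optimum for nc in niches])
    tol = np.array([nc.tolerance for nc in niches])
    amp = np.array([nc.amplitude for nc in niches])
    sens = np.array([nc.secondary_sensitivity for nc in niches])
    log_resp = np.log(amp) - (sst - opt) ** 2 / (2 * tol**2) + sens * secondary
    log_resp -= log_resp.max()
    resp = np.exp(log_resp)
    total = resp.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateSampleError(f"no species responds at {sst} °C")
    return resp / total


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(site_id.encode())])
    )


def simulate_series(
    site: SiteConfig,
    niches: Sequence[SpeciesNiche],
    forcing: ForcingCurve,
    seed: int,
    taxonomy: Taxonomy | None = None,
) -> SiteSeries:
    """Draw one site's census series: multinomial counts at each age."""
    taxonomy = taxonomy or default_taxonomy()
    if len(niches) != len(taxonomy):
        raise ConfigError("need one niche per taxon")
    if not site.sampling_ages:
        raise ConfigError(f"site {site.site_id!r} has no sampling ages")
    rng = _site_rng(seed, site.site_id)
    samples = []
    for age in sorted(site.sampling_ages):
        sst = float(local_sst(site, forcing, age))
        sec = float(site.secondary.value(age)) if site.secondary is not None else 0.0
        p = expected_proportions(niches, sst, sec)
        counts = rng.multinomial(site.count_depth, p)
        samples.append(
            AssemblageSample(
                site_id=site.site_id,
                latitude=site.latitude,
                longitude=site.longitude,
                age=float(age),
                abundance=counts.astype(float),
                taxonomy=taxonomy,
            )
        )
    return SiteSeries(
        site_id=site.site_id,
        latitude=site.latitude,
        longitude=site.longitude,
        samples=tuple(samples),
    )


# ---------------------------------------------------------------------------
# whole-dataset simulation

@dataclass(frozen=True)
class DatasetConfig:
    """Study-design parameters for a whole synthetic dataset.

    Defaults mirror the observational design the analyses target:
    25 sites spanning 0–65° N, sampled 0–24 ka every 0.6 kyr at census
    depth 300, glacial cooling amplified towards high latitudes
    (essentially no tropical cooling), a −4 °C Heinrich-like event at
    15–17 ka at mid-latitude sites, and the secondary (no-analogue)
    driver switched off.
    """

    n_sites: int = 25
    lat_min: float = 0.0
    lat_max: float = 65.0
    age_max: float = 24.0
    sampling_step: float = 0.6
    count_depth: int = 300
    glacial_anomaly: float = -6.0
    deglaciation: tuple[float, float] = (11.0, 17.0)
    heinrich_enabled: bool = True
    heinrich_lat_band: tuple[float, float] = (38.0, 52.0)
    heinrich_window: tuple[float, float] = (15.0, 17.0)
    heinrich_delta_t: float = -4.0
    secondary_enabled: bool = False
    secondary_onset: float = 11.0
    secondary_lat_band: tuple[float, float] = (30.0, 50.0)
    secondary_strength: float = 2.0
    secondary_timescale: float = 1.0
    lgm_window: tuple[float, float] = (19.0, 23.0)

    def modern_sst(self, latitude) -> np.ndarray:
        """Modern annual-mean SST transect: 29 °C at the equator, ~3 °C at 65° N."""
        latitude = np.asarray(latitude, dtype=float)
        return 29.0 - 26.0 * latitude / 65.0

    def cooling_scale(self, latitude) -> np.ndarray:
        """Polar-amplified glacial cooling, ≈0 at the equator.

        Quadratic in latitude so the glacial tropics stay close to their
        modern state and the glacial reference pool spans the full range
        of temperatures any later sample experiences.
        """
        latitude = np.asarray(latitude, dtype=float)
        return 3.3 * (latitude / 65.0) ** 2


def default_site_configs(config: DatasetConfig | None = None) -> list[SiteConfig]:
    config = config or DatasetConfig()
    if config.n_sites < 2:
        raise ConfigError("need at least 2 sites")
    lats = np.linspace(config.lat_min, config.lat_max, config.n_sites)
    ages = tuple(np.round(np.arange(0.0, config.age_max + 1e-9, config.sampling_step), 9))
    sites = []
    for i, lat in enumerate(lats):
        heinrich = None
        if config.heinrich_enabled and config.heinrich_lat_band[0] <= lat <= config.heinrich_lat_band[1]:
            heinrich = HeinrichEvent(
                t_start=config.heinrich_window[0],
                t_end=config.heinrich_window[1],
                delta_t=config.heinrich_delta_t,
            )
        secondary = None
        if config.secondary_enabled and config.secondary_lat_band[0] <= lat <= config.secondary_lat_band[1]:
            secondary = SecondaryDriver(
                onset=config.secondary_onset,
                strength=config.secondary_strength,
                timescale=config.secondary_timescale,
            )
        sites.append(
            SiteConfig(
                site_id=f"SYN-{i:02d}",
                latitude=float(lat),
                modern_sst=float(config.modern_sst(lat)),
                glacial_cooling_scale=float(config.cooling_scale(lat)),
                heinrich_event=heinrich,
                sampling_ages=ages,
                count_depth=config.count_depth,
                secondary=secondary,
            )
        )
    return sites


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator actually imposed, for recovery scoring."""

    niches: tuple[SpeciesNiche, ...]
    forcing: ForcingCurve
    sst_history: Mapping[str, np.ndarray]
    expected: Mapping[str, np.ndarray]  # site_id -> (n_ages, n_taxa) proportions
    sampling_ages: Mapping[str, np.ndarray]
    no_analogue_onset: Mapping[str, float | None]

    def affected_sites(self) -> list[str]:
        return [s for s, onset in self.no_analogue_onset.items() if onset is not None]


def simulate_dataset(
    config: DatasetConfig | None = None,
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
) -> tuple[list[SiteSeries], ReferenceSet, SyntheticTruth]:
    """Simulate all sites, build the glacial reference set, record truth."""
    config = config or DatasetConfig()
    taxonomy = taxonomy or default_taxonomy()
    niches = default_niches(taxonomy)
    forcing = make_forcing(
        glacial_anomaly=config.glacial_anomaly,
        deglaciation=config.deglaciation,
        age_max=config.age_max,
    )
    sites = default_site_configs(config)

    series_list = []
    sst_hist: dict[str, np.ndarray] = {}
    expected: dict[str, np.ndarray] = {}
    ages_map: dict[str, np.ndarray] = {}
    onsets: dict[str, float | None] = {}
    for site in sites:
        series_list.append(simulate_series(site, niches, forcing, seed, taxonomy))
        ages = np.array(sorted(site.sampling_ages))
        ssts = local_sst(site, forcing, ages)
        secs = site.secondary.value(ages) if site.secondary is not None else np.zeros_like(ages)
        expected[site.site_id] = np.vstack(
            [expected_proportions(niches, float(t), float(s)) for t, s in zip(ssts, secs)]
        )
        sst_hist[site.site_id] = ssts
        ages_map[site.site_id] = ages
        onsets[site.site_id] = site.secondary.onset if site.secondary is not None else None

    reference = build_reference_set(series_list, window=config.lgm_window)
    truth = SyntheticTruth(
        niches=niches,
        forcing=forcing,
        sst_history=sst_hist,
        expected=expected,
        sampling_ages=ages_map,
        no_analogue_onset=onsets,
    )
    return series_list, reference, truth


# ---------------------------------------------------------------------------
# targeted scenario for rate-recovery tests

def simulate_richness_trend(
    slope: float,
    seed: int,
    *,
    baseline_richness: int = 15,
    age_max: float = 24.0,
    sampling_step: float = 0.6,
    count_depth: int = 300,
    taxonomy: Taxonomy | None = None,
) -> tuple[SiteSeries, float]:
    """A series whose true richness changes linearly through time.

    The number of species present at age a is
    ``round(baseline_richness + slope * (age_max - a))`` (slope in
    species per kyr toward the present); present species get even
    expected abundances and counts are multinomial.  Returns the series
    and the imposed slope, for parameter-recovery tests of the rate
    estimators.
    """
    taxonomy = taxonomy or default_taxonomy()
    n_taxa = len(taxonomy)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x52415445]))
    order = rng.permutation(n_taxa)
    ages = np.round(np.arange(0.0, age_max + 1e-9, sampling_step), 9)
    samples = []
    for age in ages:
        k = int(round(baseline_richness + slope * (age_max - age)))
        if not 1 <= k <= n_taxa:
            raise ConfigError(
                f"imposed richness {k} outside [1, {n_taxa}] at {age} ka; "
                "adjust baseline_richness or slope"
            )
        p = np.zeros(n_taxa)
        p[order[:k]] = 1.0 / k
        counts = rng.multinomial(count_depth, p)
        samples.append(
            AssemblageSample(
                site_id="TREND",
                latitude=40.0,
                longitude=-30.0,
                age=float(age),
                abundance=counts.astype(float),
                taxonomy=taxonomy,
            )
        )
    series = SiteSeries(site_id="TREND", latitude=40.0, longitude=-30.0, samples=tuple(samples))
    return series, float(slope)
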