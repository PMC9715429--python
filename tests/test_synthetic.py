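"""The synthetic assemblage generator and its ground-truth record."""

import numpy as np
import pytest

from foramshift import (
    DatasetConfig,
    HeinrichEvent,
    SecondaryDriver,
    SiteConfig,
    SpeciesNiche,
    default_niches,
    default_taxonomy,
    expected_proportions,
    local_sst,
    make_forcing,
    morisita_horn,
    simulate_dataset,
    simulate_richness_trend,
    simulate_series,
)
from foramshift.errors import ConfigError, DegenerateSampleError, ValidationError


class TestForcing:
    def test_glacial_plateau_is_flat(self):
        f = make_forcing()
        plateau = f.gmst_anomaly[(f.ages >= 17) & (f.ages <= 23)]
        assert np.ptp(plateau) == 0.0

    def test_warming_sign(self):
        f = make_forcing()
        assert f.anomaly(20.0) < f.anomaly(5.0)

    def test_referenced_to_late_holocene_mean(self):
        f = make_forcing()
        recent = f.gmst_anomaly[f.ages <= 2.0]
        assert abs(recent.mean()) < 1e-9

    def test_monotone_through_deglaciation(self):
        f = make_forcing()
        ramp = f.gmst_anomaly[(f.ages >= 11) & (f.ages <= 17)]
        assert (np.diff(ramp) <= 1e-12).all()  # cooling backwards in time

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigError):
            make_forcing(deglaciation=(17.0, 11.0))

    def test_age_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            make_forcing().anomaly(30.0)


class TestLocalSst:
    def _site(self, **kw):
        defaults = dict(site_id="S", latitude=40.0, modern_sst=15.0,
                        glacial_cooling_scale=1.0, sampling_ages=(0.0,))
        defaults.update(kw)
        return SiteConfig(**defaults)

    def test_zero_coupling_keeps_modern_sst(self):
        f = make_forcing()
        site = self._site(glacial_cooling_scale=0.0)
        ages = np.array([0.0, 10.0, 20.0])
        np.testing.assert_allclose(local_sst(site, f, ages), 15.0)

    def test_heinrich_offset_is_additive_inside_window(self):
        f = make_forcing()
        ev = HeinrichEvent(t_start=15.0, t_end=17.0, delta_t=-4.0)
        base = self._site(glacial_cooling_scale=0.0)
        hit = self._site(heinrich_event=ev, glacial_cooling_scale=0.0)
        assert local_sst(hit, f, 16.0) == local_sst(base, f, 16.0) - 4.0
        assert local_sst(hit, f, 5.0) == local_sst(base, f, 5.0)

    def test_cooling_scale_is_linear(self):
        f = make_forcing()
        one = self._site(glacial_cooling_scale=1.0)
        two = self._site(glacial_cooling_scale=2.0)
        contrast_one = local_sst(one, f, 1.0) - local_sst(one, f, 20.0)
        contrast_two = local_sst(two, f, 1.0) - local_sst(two, f, 20.0)
        assert contrast_two == pytest.approx(2 * contrast_one)

    def test_floor_at_freezing(self):
        f = make_forcing()
        cold = self._site(modern_sst=2.0, glacial_cooling_scale=3.0)
        assert local_sst(cold, f, 20.0) == -2.0


class TestExpectedProportions:
    def test_single_species_normalizes_to_one(self):
        (p,) = expected_proportions([SpeciesNiche("a", 10.0, 2.0)], sst=25.0)
        assert p == 1.0

    def test_identical_niches_split_evenly(self):
        niches = [SpeciesNiche("a", 10.0, 2.0), SpeciesNiche("b", 10.0, 2.0)]
        np.testing.assert_allclose(expected_proportions(niches, 14.0), [0.5, 0.5])

    def test_matched_optimum_dominates(self):
        # responses exp(0) vs exp(-50): ratio astronomically in favour of the first
        niches = [SpeciesNiche("warm", 25.0, 2.0), SpeciesNiche("cold", 5.0, 2.0)]
        p = expected_proportions(niches, 25.0)
        expected = np.array([1.0, np.exp(-50.0)])
        np.testing.assert_allclose(p, expected / expected.sum(), rtol=1e-12)

    def test_secondary_axis_reweights(self):
        niches = [
            SpeciesNiche("up", 10.0, 3.0, secondary_sensitivity=1.0),
            SpeciesNiche("down", 10.0, 3.0, secondary_sensitivity=-1.0),
        ]
        p = expected_proportions(niches, 10.0, secondary=0.5)
        assert p[0] / p[1] == pytest.approx(np.exp(1.0))

    def test_sums_to_one_across_conditions(self):
        niches = default_niches()
        for sst in (-2.0, 4.0, 13.0, 29.0):
            assert expected_proportions(niches, sst).sum() == pytest.approx(1.0)

    def test_invalid_niche_rejected(self):
        with pytest.raises(ConfigError):
            SpeciesNiche("bad", 10.0, tolerance=0.0)


class TestSimulateSeries:
    def _setup(self, count_depth=300, ages=(0.0, 12.0, 24.0)):
        tax = default_taxonomy()
        site = SiteConfig(site_id="S", latitude=40.0, modern_sst=15.0,
                          glacial_cooling_scale=1.0, sampling_ages=tuple(ages),
                          count_depth=count_depth)
        return site, default_niches(tax), make_forcing(), tax

    def test_counts_sum_to_depth(self):
        site, niches, forcing, tax = self._setup()
        series = simulate_series(site, niches, forcing, seed=1, taxonomy=tax)
        for s in series.samples:
            assert s.abundance.sum() == 300

    def test_same_seed_reproduces_identical_counts(self):
        site, niches, forcing, tax = self._setup()
        a = simulate_series(site, niches, forcing, seed=9, taxonomy=tax)
        b = simulate_series(site, niches, forcing, seed=9, taxonomy=tax)
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.abundance, sb.abundance)

    def test_large_depth_converges_to_expected(self):
        site, niches, forcing, tax = self._setup(count_depth=10_000_000, ages=(5.0,))
        series = simulate_series(site, niches, forcing, seed=2, taxonomy=tax)
        expected = expected_proportions(niches, float(local_sst(site, forcing, 5.0)))
        np.testing.assert_allclose(series.samples[0].proportions(), expected, atol=1e-2)

    def test_stationary_noise_only_drift_is_small(self):
        # constant forcing, depth 10k: first-vs-last M-H is sampling noise only
        tax = default_taxonomy()
        site = SiteConfig(site_id="S", latitude=40.0, modern_sst=15.0,
                          glacial_cooling_scale=0.0,
                          sampling_ages=tuple(np.arange(0.0, 24.1, 0.6)),
                          count_depth=10_000)
        series = simulate_series(site, default_niches(tax), make_forcing(), seed=3,
                                 taxonomy=tax)
        d = morisita_horn(series.samples[0].proportions(), series.samples[-1].proportions())
        assert d < 0.05


class TestSimulateDataset:
    def test_default_shapes(self):
        series, ref, truth = simulate_dataset(seed=1)
        assert len(series) == 25
        assert all(len(sr) == 41 for sr in series)
        assert len(ref) == 25 * 7  # seven sampling ages inside 19-23 ka per site

    def test_truth_records_no_onsets_by_default(self):
        _, _, truth = simulate_dataset(seed=1)
        assert truth.affected_sites() == []

    def test_secondary_driver_onsets_recorded_for_band(self):
        cfg = DatasetConfig(secondary_enabled=True)
        series, _, truth = simulate_dataset(cfg, seed=1)
        affected = truth.affected_sites()
        assert affected, "mid-latitude band must contain sites"
        lats = {sr.site_id: sr.latitude for sr in series}
        for sid in affected:
            assert 30.0 <= lats[sid] <= 50.0
            assert truth.no_analogue_onset[sid] == 11.0

    def test_truth_expected_proportions_sum_to_one(self):
        _, _, truth = simulate_dataset(seed=1)
        for exp in truth.expected.values():
            np.testing.assert_allclose(exp.sum(axis=1), 1.0, atol=1e-12)

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dataset(DatasetConfig(n_sites=1), seed=1)

    def test_dataset_determinism(self):
        a, _, _ = simulate_dataset(seed=5)
        b, _, _ = simulate_dataset(seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(
                np.vstack([s.abundance for s in sa.samples]),
                np.vstack([s.abundance for s in sb.samples]),
            )


class TestSecondaryDriver:
    def test_zero_before_onset_saturating_after(self):
        d = SecondaryDriver(onset=11.0, strength=2.0, timescale=1.0)
        assert d.value(15.0) == 0.0
        assert d.value(11.0) == 0.0
        assert 0 < d.value(10.5) < d.value(5.0) < 2.0


class TestRichnessTrendScenario:
    def test_imposed_richness_is_linear_in_time(self):
        series, slope = simulate_richness_trend(0.4, seed=0)
        from foramshift import richness

        rich = np.array([richness(s) for s in series.samples])
        ages = series.ages
        # expected richness at the oldest and newest samples
        assert rich[-1] == pytest.approx(15, abs=1)
        assert rich[0] == pytest.approx(15 + 0.4 * 24, abs=1.5)
        assert slope == 0.4

    def test_out_of_range_richness_rejected(self):
        with pytest.raises(ConfigError):
            simulate_richness_trend(2.0, seed=0)  # would exceed the taxon pool
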