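"""Taxonomy harmonization, table round-trips, windows and reference sets."""

import numpy as np
import pandas as pd
import pytest

from foramshift import (
    Taxonomy,
    build_reference_set,
    default_taxonomy,
    filter_time_window,
    load_assemblage_table,
    to_relative_abundance,
    write_assemblage_table,
)
from foramshift.errors import (
    DegenerateSampleError,
    EmptyReferenceError,
    FormatError,
    UnknownTaxonError,
    ValidationError,
)


class TestTaxonomy:
    def test_default_has_41_unique_canonical_taxa(self):
        tax = default_taxonomy()
        assert len(tax) == 41
        assert len(set(tax.species_names)) == 41

    def test_chromotype_and_intergrade_merges(self):
        tax = default_taxonomy()
        assert tax.canonicalize("Globigerinoides ruber albus") == "Globigerinoides ruber"
        assert tax.canonicalize("Globigerinoides ruber ruber") == "Globigerinoides ruber"
        assert tax.canonicalize("P/D intergrade") == "Neogloboquadrina incompta"

    def test_canonicalize_is_idempotent(self):
        tax = default_taxonomy()
        for source in tax.merge_rules:
            once = tax.canonicalize(source)
            assert tax.canonicalize(once) == once

    def test_unknown_taxon_raises(self):
        tax = default_taxonomy()
        with pytest.raises(UnknownTaxonError):
            tax.canonicalize("Tyrannosaurus rex")

    def test_duplicate_canonical_labels_rejected(self):
        with pytest.raises(ValidationError):
            Taxonomy(species_names=("A", "A"))

    def test_merge_rule_must_target_canonical_label(self):
        with pytest.raises(ValidationError):
            Taxonomy(species_names=("A",), merge_rules={"B": "C"})


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "raw, expected",
        [((2, 2, 4), (0.25, 0.25, 0.5)), ((1, 0, 0), (1, 0, 0)), ((3,), (1.0,))],
    )
    def test_normalization(self, raw, expected):
        np.testing.assert_allclose(to_relative_abundance(raw), expected)

    def test_all_zero_vector_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            to_relative_abundance([0.0, 0.0, 0.0])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError):
            to_relative_abundance([1.0, -0.5])


class TestLoadTable:
    def _write(self, tmp_path, df):
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        return path

    def test_chromotypes_merge_and_conserve_total(self, tmp_path):
        tax = default_taxonomy()
        df = pd.DataFrame(
            {"site_id": ["X"], "latitude": [40.0], "longitude": [-30.0],
             "age_ka": [5.0], "G. ruber ruber": [5], "G. ruber albus": [3]}
        )
        (sample,) = load_assemblage_table(self._write(tmp_path, df), tax)
        assert sample.abundance[tax.index("Globigerinoides ruber")] == 8
        assert sample.abundance.sum() == 8  # merging conserves total abundance

    def test_unlisted_taxa_filled_with_zero(self, tmp_path):
        tax = default_taxonomy()
        cols = {name: [1] for name in tax.species_names[:10]}
        df = pd.DataFrame(
            {"site_id": ["X"], "latitude": [0.0], "longitude": [0.0], "age_ka": [1.0], **cols}
        )
        (sample,) = load_assemblage_table(self._write(tmp_path, df), tax)
        assert len(sample.abundance) == 41
        assert np.count_nonzero(sample.abundance == 0) == 31

    def test_empty_table_gives_empty_list(self, tmp_path):
        df = pd.DataFrame(columns=["site_id", "latitude", "longitude", "age_ka"])
        assert load_assemblage_table(self._write(tmp_path, df), default_taxonomy()) == []

    def test_missing_metadata_column_is_format_error(self, tmp_path):
        df = pd.DataFrame({"site_id": ["X"], "age_ka": [1.0]})
        with pytest.raises(FormatError):
            load_assemblage_table(self._write(tmp_path, df), default_taxonomy())

    def test_unknown_taxon_column_errors_or_drops(self, tmp_path):
        tax = default_taxonomy()
        df = pd.DataFrame(
            {"site_id": ["X"], "latitude": [0.0], "longitude": [0.0], "age_ka": [1.0],
             "Orbulina universa": [4], "Mystery species": [2]}
        )
        path = self._write(tmp_path, df)
        with pytest.raises(UnknownTaxonError):
            load_assemblage_table(path, tax)
        with pytest.warns(UserWarning, match="Mystery"):
            (sample,) = load_assemblage_table(path, tax, on_unknown="drop")
        assert sample.abundance.sum() == 4

    def test_percent_units_renormalized_with_tolerance(self, tmp_path):
        tax = default_taxonomy()
        df = pd.DataFrame(
            {"site_id": ["X"], "latitude": [0.0], "longitude": [0.0], "age_ka": [1.0],
             "Orbulina universa": [60.2], "Globigerina bulloides": [40.1]}
        )
        (sample,) = load_assemblage_table(self._write(tmp_path, df), tax, units="percent")
        assert sample.abundance.sum() == pytest.approx(1.0)

    def test_percent_rows_far_from_100_rejected(self, tmp_path):
        tax = default_taxonomy()
        df = pd.DataFrame(
            {"site_id": ["X"], "latitude": [0.0], "longitude": [0.0], "age_ka": [1.0],
             "Orbulina universa": [60.0], "Globigerina bulloides": [20.0]}
        )
        with pytest.raises(ValidationError):
            load_assemblage_table(self._write(tmp_path, df), tax, units="percent")

    def test_roundtrip_is_identity(self, tmp_path):
        tax = default_taxonomy()
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"site_id": ["A", "A", "B"], "latitude": [10.0, 10.0, 55.0],
             "longitude": [-20.0, -20.0, -30.0], "age_ka": [1.5, 8.0, 3.25]}
        )
        for name in tax.species_names:
            df[name] = rng.integers(0, 50, size=3)
        first = load_assemblage_table(self._write(tmp_path, df), tax)
        out = tmp_path / "rt.csv"
        write_assemblage_table(first, out)
        second = load_assemblage_table(out, tax)
        for a, b in zip(first, second):
            assert a.sample_id == b.sample_id
            np.testing.assert_array_equal(a.abundance, b.abundance)


class TestTimeWindow:
    def test_closed_interval_membership(self, make_sample):
        samples = [make_sample([1], age=a) for a in (2.0, 19.0, 20.0, 23.0, 25.0)]
        kept = filter_time_window(samples, 19.0, 23.0)
        assert [s.age for s in kept] == [19.0, 20.0, 23.0]  # endpoints included

    def test_empty_input_empty_output(self):
        assert filter_time_window([], 19, 23) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(ValidationError):
            filter_time_window([], 23, 19)


class TestReferenceSet:
    def test_union_of_external_and_in_window(self, make_sample, make_series):
        external = [make_sample([1, 1], age=a, site_id="EXT") for a in (19.5, 20.5, 21.5)]
        series = make_series([(18.0, [1, 2]), (20.0, [2, 1]), (22.0, [1, 1]), (24.0, [3, 1])])
        ref = build_reference_set([series], external)
        assert len(ref) == 5  # 3 external + ages 20 and 22 from the series

    def test_duplicates_by_site_and_age_removed(self, make_sample, make_series):
        series = make_series([(20.0, [2, 1]), (22.0, [1, 1])])
        dup = make_sample([9, 9], age=20.0, site_id="S1")
        ref = build_reference_set([series], [dup])
        assert len(ref) == 2

    def test_window_excluding_series_keeps_external_only(self, make_sample, make_series):
        external = [make_sample([1], age=20.0, site_id="EXT")]
        series = make_series([(1.0, [1, 2]), (5.0, [2, 1])])
        ref = build_reference_set([series], external)
        assert len(ref) == 1

    def test_empty_reference_is_an_error(self, make_series):
        series = make_series([(1.0, [1, 2]), (5.0, [2, 1])])
        with pytest.raises(EmptyReferenceError):
            build_reference_set([series])

    def test_out_of_window_reference_sample_rejected(self, make_sample):
        from foramshift import ReferenceSet

        with pytest.raises(ValidationError):
            ReferenceSet(samples=(make_sample([1], age=5.0),), window=(19.0, 23.0))


class TestSeriesInvariants:
    def test_tied_ages_are_an_error(self, make_sample):
        from foramshift import SiteSeries

        s1 = make_sample([1], age=2.0)
        s2 = make_sample([2], age=2.0)
        with pytest.raises(ValidationError):
            SiteSeries(site_id="S1", latitude=40.0, longitude=-30.0, samples=(s1, s2))

    def test_foreign_sample_rejected(self, make_sample):
        from foramshift import SiteSeries

        s1 = make_sample([1], age=2.0, site_id="OTHER")
        with pytest.raises(ValidationError):
            SiteSeries(site_id="S1", latitude=40.0, longitude=-30.0, samples=(s1,))
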