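import numpy as np
import pytest

from foramshift import AssemblageSample, SiteSeries, Taxonomy, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Five-taxon taxonomy for hand-checkable cases."""
    return Taxonomy(species_names=("A", "B", "C", "D", "E"))


@pytest.fixture
def make_sample(toy_taxonomy, taxonomy):
    """Factory for toy samples: make_sample([1,2,0,0,0], age=5.0).

    Short abundance lists are padded with zeros on the 5-taxon toy
    taxonomy; longer ones on the full 41-taxon taxonomy.
    """

    def _make(abundance, age=0.0, site_id="S1", latitude=40.0, longitude=-30.0,
              taxonomy=None, _toy=toy_taxonomy, _full=taxonomy):
        if taxonomy is None:
            taxonomy = _toy if len(abundance) <= len(_toy) else _full
        a = np.zeros(len(taxonomy))
        a[: len(abundance)] = abundance
        return AssemblageSample(
            site_id=site_id, latitude=latitude, longitude=longitude,
            age=age, abundance=a, taxonomy=taxonomy,
        )

    return _make


@pytest.fixture
def make_series(make_sample):
    """Factory for a toy series from (age, abundance) pairs."""

    def _make(age_abundances, site_id="S1", latitude=40.0, taxonomy=None):
        longest = max(len(ab) for _, ab in age_abundances)
        samples = tuple(
            make_sample(
                list(ab) + [0] * (longest - len(ab)),
                age=age, site_id=site_id, latitude=latitude, taxonomy=taxonomy,
            )
            for age, ab in sorted(age_abundances)
        )
        return SiteSeries(site_id=site_id, latitude=latitude, longitude=-30.0,
                          samples=samples)

    return _make


def random_proportions(rng, n_taxa):
    """A strictly valid composition with a random support pattern."""
    v = rng.gamma(0.5, size=n_taxa) * (rng.random(n_taxa) < 0.7)
    if v.sum() == 0:
        v[rng.integers(n_taxa)] = 1.0
    return v / v.sum()
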