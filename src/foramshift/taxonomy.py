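"""Harmonized taxonomy for planktonic foraminifera census data.

Assemblage counts from different studies use inconsistent species labels:
some report *Globigerinoides ruber* chromotypes separately, some lump
morphological intermediates ("P/D intergrades") with one of their end
members, and older names survive in legacy tables.  A :class:`Taxonomy`
fixes an ordered list of canonical taxon labels plus a mapping from source
labels to canonical ones, so that every census is expressed on the same
41-dimensional abundance vector before any dissimilarity or diversity
computation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .errors import UnknownTaxonError, ValidationError


@dataclass(frozen=True)
class Taxonomy:
    """Ordered canonical taxon list plus source-label merge rules.

    Parameters
    ----------
    species_names
        Canonical taxon labels, ordered; this order defines the layout of
        every abundance vector in the package.
    merge_rules
        Mapping from a source label (as found in an input table) to the
        canonical label it harmonizes into.  Canonical labels themselves
        need not appear as keys.
    """

    species_names: tuple[str, ...]
    merge_rules: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.species_names)) != len(self.species_names):
            raise ValidationError("canonical taxon labels must be unique")
        unknown_targets = set(self.merge_rules.values()) - set(self.species_names)
        if unknown_targets:
            raise ValidationError(
                f"merge rules target labels outside the canonical list: "
                f"{sorted(unknown_targets)}"
            )

    def __len__(self) -> int:
        return len(self.species_names)

    def index(self, label: str) -> int:
        return self.species_names.index(label)

    def canonicalize(self, label: str) -> str:
        """Map a source label to its canonical label.

        Canonical labels map to themselves; anything else must be covered
        by a merge rule, otherwise :class:`UnknownTaxonError` is raised.
        Harmonization is idempotent by construction: the output is always
        a canonical label, and canonical labels are fixed points.
        """
        if label in self.merge_rules:
            return self.merge_rules[label]
        if label in self.species_names:
            return label
        raise UnknownTaxonError(f"unknown taxon label: {label!r}")

    def resolve(self, labels: Iterable[str], *, on_unknown: str = "error") -> dict[str, str | None]:
        """Canonicalize many labels at once.

        ``on_unknown`` is ``"error"`` (default, raise) or ``"drop"``
        (map unknown labels to ``None`` so callers can discard them).
        """
        out: dict[str, str | None] = {}
        for label in labels:
            try:
                out[label] = self.canonicalize(label)
            except UnknownTaxonError:
                if on_unknown == "drop":
                    out[label] = None
                else:
                    raise
        return out


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("foramshift.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def default_taxonomy() -> Taxonomy:
    """The package's bundled 41-taxon harmonized taxonomy.

    Canonical list and merge rules are shipped as CSV package data;
    the merges include the chromotype merge into *Globigerinoides ruber*
    and the P/D-intergrade merge into *Neogloboquadrina incompta*.
    """
    names = tuple(row["canonical_label"] for row in _read_packaged_csv("taxa.csv"))
    rules = {
        row["source_label"]: row["canonical_label"]
        for row in _read_packaged_csv("merge_rules.csv")
    }
    return Taxonomy(species_names=names, merge_rules=rules)


def load_taxonomy(taxa_path, merge_rules_path=None) -> Taxonomy:
    """Load a taxonomy from user CSV files.

    ``taxa_path`` needs a ``canonical_label`` column; the optional merge
    rules file needs ``source_label`` and ``canonical_label`` columns.
    """
    with open(taxa_path, newline="") as fh:
        names = tuple(row["canonical_label"] for row in csv.DictReader(fh))
    rules: dict[str, str] = {}
    if merge_rules_path is not None:
        with open(merge_rules_path, newline="") as fh:
            for row in csv.DictReader(fh):
                rules[row["source_label"]] = row["canonical_label"]
    return Taxonomy(species_names=names, merge_rules=rules)
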