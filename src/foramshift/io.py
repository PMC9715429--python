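"""Reading and writing assemblage tables.

The on-disk schema is one row per census sample:

    site_id, latitude, longitude, age_ka, <taxon 1>, <taxon 2>, ...

Taxon columns may be any subset of the taxonomy (missing taxa are zero —
species not reported are treated as absent) and may use source labels
covered by the taxonomy's merge rules; merged columns are summed, so total
abundance is conserved by harmonization.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .samples import AssemblageSample, group_into_series
from .taxonomy import Taxonomy

METADATA_COLUMNS = ("site_id", "latitude", "longitude", "age_ka")


def load_assemblage_table(
    path,
    taxonomy: Taxonomy,
    *,
    units: str = "counts",
    on_unknown: str = "error",
    sep: str = ",",
) -> list[AssemblageSample]:
    """Read a delimited census table and harmonize it onto ``taxonomy``.

    Parameters
    ----------
    units
        ``"counts"`` (raw counts, kept as is), ``"percent"`` (rows must sum
        to 100 within [99, 101] and are renormalized to proportions) or
        ``"proportions"`` (rows renormalized, must sum to 1 ± 0.01).
    on_unknown
        ``"error"`` (default): a taxon column that is neither canonical nor
        in the merge rules raises; ``"drop"``: it is discarded with a warning.
    """
    if units not in ("counts", "percent", "proportions"):
        raise ValidationError(f"unknown units {units!r}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata column(s): {missing}")
    if df.empty:
        return []

    taxon_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    resolved = taxonomy.resolve(taxon_cols, on_unknown=on_unknown)
    dropped = [c for c, canon in resolved.items() if canon is None]
    if dropped:
        warnings.warn(f"dropping unknown taxon column(s): {dropped}")

    n = len(df)
    abundance = np.zeros((n, len(taxonomy)))
    for col, canon in resolved.items():
        if canon is None:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").fillna(0.0).to_numpy()
        abundance[:, taxonomy.index(canon)] += vals
    if np.any(abundance < 0):
        raise ValidationError("negative abundance in input table")

    if units in ("percent", "proportions"):
        target, tol = (100.0, 1.0) if units == "percent" else (1.0, 0.01)
        sums = abundance.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - target) > tol)
        if bad.size:
            raise ValidationError(
                f"{units} rows {bad.tolist()} sum to {sums[bad]} "
                f"(expected {target} ± {tol})"
            )
        abundance = abundance / sums[:, None]

    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        samples.append(
            AssemblageSample(
                site_id=str(getattr(row, "site_id")),
                latitude=float(getattr(row, "latitude")),
                longitude=float(getattr(row, "longitude")),
                age=float(getattr(row, "age_ka")),
                abundance=abundance[i],
                taxonomy=taxonomy,
            )
        )
    return samples


def write_assemblage_table(samples: Sequence[AssemblageSample], path, *, sep: str = ",") -> None:
    """Write samples in the canonical schema (one column per canonical taxon)."""
    if not samples:
        pd.DataFrame(columns=list(METADATA_COLUMNS)).to_csv(path, sep=sep, index=False)
        return
    taxonomy = samples[0].taxonomy
    rows = []
    for s in samples:
        row = {
            "site_id": s.site_id,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "age_ka": s.age,
        }
        row.update(dict(zip(taxonomy.species_names, s.abundance)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_site_series(path, taxonomy: Taxonomy, **kwargs) -> list:
    """Load a table and group it into per-site, age-ordered series."""
    return group_into_series(load_assemblage_table(path, taxonomy, **kwargs))
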