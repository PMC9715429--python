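"""Morisita-Horn compositional dissimilarity and its low-dimensional view.

The Morisita-Horn (M-H) index between two compositions x and y (relative
abundances over the same taxon list) is

    C = 1 - 2 * sum_i(x_i * y_i) / (sum_i x_i^2 + sum_i y_i^2)

C = 0 for identical compositions, C = 1 when no species is shared.  It is
abundance-weighted, dominated by the common species, and therefore robust
to under-sampling of rare taxa — the reason it is the measure of choice
for census data of unequal size.

The pairwise M-H matrix over all samples is reduced with a PCA (each
sample's row of distances is its feature vector, column-centred, no
scaling) and the first three axes are mapped to RGB channels so that an
assemblage's colour encodes its composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateSampleError, ValidationError
from .samples import AssemblageSample, to_relative_abundance


def morisita_horn(x, y) -> float:
    """M-H dissimilarity between two relative-abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    sx = x @ x
    sy = y @ y
    if sx == 0 or sy == 0:
        raise DegenerateSampleError("zero vector has no composition")
    return float(1.0 - 2.0 * (x @ y) / (sx + sy))


def _mh_cross(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized M-H between every row of ``p`` and every row of ``q``.

    Rows must already be proportions.  Returns an (len(p), len(q)) matrix.
    """
    sp = np.einsum("ij,ij->i", p, p)
    sq = np.einsum("ij,ij->i", q, q)
    if np.any(sp == 0) or np.any(sq == 0):
        raise DegenerateSampleError("zero vector has no composition")
    num = 2.0 * (p @ q.T)
    den = sp[:, None] + sq[None, :]
    return np.clip(1.0 - num / den, 0.0, 1.0)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric matrix of M-H distances with sample identifiers."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(sample_ids=tuple(df.index.astype(str)), values=df.to_numpy(float))


def pairwise_matrix(samples: Sequence[AssemblageSample]) -> DissimilarityMatrix:
    """M-H distance between every pair of samples."""
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples for a pairwise matrix")
    try:
        p = np.vstack([s.proportions() for s in samples])
    except DegenerateSampleError as err:
        bad = [s.sample_id for s in samples if s.abundance.sum() <= 0]
        raise DegenerateSampleError(f"degenerate sample(s): {bad}") from err
    values = _mh_cross(p, p)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DissimilarityMatrix(
        sample_ids=tuple(s.sample_id for s in samples), values=values
    )


@dataclass(frozen=True)
class PcaResult:
    """Per-sample scores on the leading axes plus variance fractions."""

    scores: np.ndarray
    explained_variance_fraction: np.ndarray


def pca_on_dissimilarity(matrix: DissimilarityMatrix, k: int = 3) -> PcaResult:
    """PCA of the dissimilarity matrix, rows as feature vectors.

    Columns are centred but not scaled.  ``k`` beyond the matrix rank is
    truncated with a warning.  For an all-zero (degenerate) matrix the
    scores are zero and the variance fractions are zero.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    v = matrix.values
    n = v.shape[0]
    centred = v - v.mean(axis=0)
    if np.abs(centred).max() < 1e-12:  # numerically constant rows
        centred = np.zeros_like(centred)
    rank = np.linalg.matrix_rank(centred) if np.any(centred) else 0
    k_eff = min(k, max(rank, 1), n)
    if k_eff < k:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; returning {k_eff} axes")
    if rank == 0:
        return PcaResult(scores=np.zeros((n, k_eff)), explained_variance_fraction=np.zeros(k_eff))
    pca = PCA(n_components=k_eff)
    scores = pca.fit_transform(v)
    return PcaResult(scores=scores, explained_variance_fraction=pca.explained_variance_ratio_)


def scores_to_rgb(scores: np.ndarray) -> np.ndarray:
    """Map 3 PCA axes to colours: axis 1 → blue, axis 2 → red, axis 3 → green.

    Each axis is min-max rescaled to [0, 1] over the sample set; a constant
    axis carries no information and is fixed at 0.5 with a warning.
    Returns an (n, 3) array of (r, g, b) triples.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValidationError("scores must be an (n, 3) array")
    channels = np.empty_like(s)
    for j in range(3):
        lo, hi = s[:, j].min(), s[:, j].max()
        if hi == lo:
            warnings.warn(f"axis {j + 1} is constant; channel fixed at 0.5")
            channels[:, j] = 0.5
        else:
            channels[:, j] = (s[:, j] - lo) / (hi - lo)
    rgb = np.empty_like(channels)
    rgb[:, 2] = channels[:, 0]  # PC1 -> blue
    rgb[:, 0] = channels[:, 1]  # PC2 -> red
    rgb[:, 1] = channels[:, 2]  # PC3 -> green
    return rgb
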