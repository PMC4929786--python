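"""Community-level dissimilarity: storage effects and plate-vs-fecal ranking.

All comparisons use Bray–Curtis dissimilarity computed on relative
abundances, BC(p, q) = 1 - sum_i min(p_i, q_i), so unequal sequencing depth
cannot masquerade as community change.  0 means identical profiles, 1 means
disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_bc
from scipy.spatial.distance import pdist, squareform

from .io_formats import ConditionSpec, OtuTable, SampleMetadata

__all__ = [
    "DissimilarityMatrix",
    "StorageEffect",
    "bray_curtis",
    "dissimilarity_matrix",
    "storage_effect",
    "plate_vs_fecal_ranking",
]


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match sample_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly 0")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1 + 1e-12):
            raise ValueError("values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class StorageEffect:
    bc_fresh_frozen: float
    bc_fresh_aerobic: float | None = None


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray–Curtis dissimilarity of two count vectors (normalized first)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero vector has no community profile")
    return float(_scipy_bc(a / a.sum(), b / b.sum()))


def dissimilarity_matrix(table: OtuTable, sample_ids: list[str] | None = None) -> DissimilarityMatrix:
    """All-pairs Bray–Curtis over (a subset of) the table's samples."""
    ids = list(sample_ids) if sample_ids is not None else list(table.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    sub = table.subset_samples(ids)
    totals = sub.sample_totals()
    if np.any(totals == 0):
        empty = [s for s, t in zip(ids, totals) if t == 0]
        raise ValueError(f"samples with zero reads: {empty}")
    rel = sub.relative_abundance()
    mat = squareform(pdist(rel, metric="braycurtis"))
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(mat, 0.0, 1.0)
    return DissimilarityMatrix(ids, mat)


def _find_plate(
    metadata: list[SampleMetadata], donor: str, condition: ConditionSpec, storage: str
) -> SampleMetadata | None:
    for m in metadata:
        if (
            m.donor == donor
            and m.role == "plate_pool"
            and m.medium == condition.medium
            and m.atmosphere == condition.atmosphere
            and m.storage == storage
        ):
            return m
    return None


def storage_effect(
    table: OtuTable,
    metadata: list[SampleMetadata],
    donor: str,
    condition: ConditionSpec,
) -> StorageEffect:
    """Bray–Curtis between matched fresh/altered plate pools for one condition.

    Requires the fresh and frozen pools; the aerobic-exposed comparison is
    reported when such a pool exists.
    """
    fresh = _find_plate(metadata, donor, condition, "fresh")
    if fresh is None:
        raise ValueError(f"donor {donor!r}: no fresh plate pool for {condition}")
    frozen = _find_plate(metadata, donor, condition, "frozen")
    if frozen is None:
        raise ValueError(f"donor {donor!r}: no frozen plate pool for {condition}")
    bc_ff = bray_curtis(table.counts_for(fresh.sample_id), table.counts_for(frozen.sample_id))
    aerobic = _find_plate(metadata, donor, condition, "aerobic_exposed")
    bc_fa = None
    if aerobic is not None:
        bc_fa = bray_curtis(table.counts_for(fresh.sample_id), table.counts_for(aerobic.sample_id))
    return StorageEffect(bc_ff, bc_fa)


def plate_vs_fecal_ranking(
    table: OtuTable, metadata: list[SampleMetadata], donor: str
) -> list[tuple[ConditionSpec, float]]:
    """Conditions ordered by similarity of their plate pool to the fecal sample.

    Ascending Bray–Curtis: first entry is the cultured community most similar
    to the fecal composition, last the most different.  Ties break
    lexicographically by (medium, atmosphere).
    """
    fecal = [m for m in metadata if m.donor == donor and m.role == "culture_independent"]
    if not fecal:
        raise ValueError(f"donor {donor!r} has no culture-independent sample")
    fecal_counts = table.counts_for(fecal[0].sample_id)
    plates = [
        m for m in metadata if m.donor == donor and m.role == "plate_pool" and m.storage == "fresh"
    ]
    if not plates:
        raise ValueError(f"donor {donor!r} has no plate pools")
    out = [
        (m.condition, bray_curtis(table.counts_for(m.sample_id), fecal_counts)) for m in plates
    ]
    out.sort(key=lambda e: (e[1], e[0].medium, e[0].atmosphere))
    return out
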