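"""Core culture-enrichment analysis.

Which OTUs were cultured?  A single rule drives everything here: an OTU is
*cultured* for a donor iff it reaches ``min_cultured_reads`` (default 10)
reads in at least one of that donor's plate-pool samples.  The
culture-independent (fecal) sample carries no read floor — detection there is
simply count >= 1.  From the cultured calls the module derives

* the proportion of culture-independent OTUs cultured, overall and above
  relative-abundance thresholds,
* the three-way detection partition (culture-only / both / independent-only),
* the rank-abundance classification of the fecal community, and
* the dependence of the cultured proportion on culture-independent
  sequencing depth (rarefaction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AnalysisConfig, OtuTable, SampleMetadata

__all__ = [
    "CulturedCall",
    "PartitionResult",
    "RecoveryCurve",
    "RankAbundanceRecord",
    "call_cultured",
    "proportion_cultured",
    "recovery_curve",
    "partition_otus",
    "partition_from_sets",
    "partition_percentages",
    "rank_abundance",
    "rarefy",
    "depth_effect_curve",
]


@dataclass
class CulturedCall:
    otu_id: str
    cultured: bool
    supporting_conditions: list[tuple[str, str]]
    max_plate_relabund: float

    def __post_init__(self) -> None:
        if self.cultured != bool(self.supporting_conditions):
            raise ValueError("cultured flag must mirror supporting_conditions")


@dataclass
class PartitionResult:
    culture_only: frozenset[str]
    both: frozenset[str]
    independent_only: frozenset[str]
    percentages: tuple[int, int, int]

    @property
    def union_size(self) -> int:
        return len(self.culture_only) + len(self.both) + len(self.independent_only)


@dataclass
class RecoveryCurve:
    thresholds: list[float]
    proportion_cultured: list[float]
    n_otus_at_threshold: list[int]


@dataclass
class RankAbundanceRecord:
    otu_id: str
    rank: int
    relabund: float
    cultured: bool


def call_cultured(
    table: OtuTable,
    metadata: list[SampleMetadata],
    config: AnalysisConfig,
    donor: str,
    storage: str | None = "fresh",
) -> list[CulturedCall]:
    """Per-OTU cultured calls for one donor, in table OTU order.

    Only plate-pool samples are consulted (controls are excluded); by default
    only fresh-storage pools, pass ``storage=None`` to include all.
    """
    donors = {m.donor for m in metadata}
    if donor not in donors:
        raise ValueError(f"donor {donor!r} absent from metadata")
    plates = [
        m
        for m in metadata
        if m.donor == donor
        and m.role == "plate_pool"
        and (storage is None or m.storage == storage)
    ]
    if not plates:
        raise ValueError(f"donor {donor!r} has no plate_pool samples")
    idx = [table.sample_ids.index(m.sample_id) for m in plates]
    counts = table.counts[idx]  # plates x OTUs
    totals = counts.sum(axis=1).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    relab = counts / safe[:, None]
    hits = counts >= config.min_cultured_reads  # plates x OTUs
    calls: list[CulturedCall] = []
    for j, otu_id in enumerate(table.otu_ids):
        conds = sorted(
            {(plates[i].medium, plates[i].atmosphere) for i in np.flatnonzero(hits[:, j])}
        )
        calls.append(
            CulturedCall(
                otu_id=otu_id,
                cultured=bool(conds),
                supporting_conditions=conds,
                max_plate_relabund=float(relab[:, j].max()) if len(plates) else 0.0,
            )
        )
    return calls


def proportion_cultured(
    independent_counts: np.ndarray,
    calls: list[CulturedCall],
    threshold: float = 0.0,
) -> tuple[float, int]:
    """Proportion of above-threshold culture-independent OTUs that were cultured.

    ``independent_counts`` must be aligned with ``calls`` (both in table OTU
    order).  Relative abundance is count / total reads of the
    culture-independent sample; threshold 0 means every OTU observed there
    (count >= 1).
    """
    independent_counts = np.asarray(independent_counts)
    if len(independent_counts) != len(calls):
        raise ValueError("independent_counts and calls must be aligned")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    total = independent_counts.sum()
    if total == 0:
        raise ValueError("no OTUs above threshold")
    relab = independent_counts / total
    considered = relab > threshold
    n = int(considered.sum())
    if n == 0:
        raise ValueError("no OTUs above threshold")
    cultured = np.fromiter((c.cultured for c in calls), dtype=bool, count=len(calls))
    return float(cultured[considered].sum() / n), n


def recovery_curve(
    independent_counts: np.ndarray,
    calls: list[CulturedCall],
    thresholds: list[float],
) -> RecoveryCurve:
    props, ns = [], []
    for t in thresholds:
        p, n = proportion_cultured(independent_counts, calls, t)
        props.append(p)
        ns.append(n)
    return RecoveryCurve(list(thresholds), props, ns)


def partition_percentages(n_culture_only: int, n_both: int, n_independent_only: int) -> tuple[int, int, int]:
    """Integer percentages of the union, rounded half-up."""
    union = n_culture_only + n_both + n_independent_only
    if union == 0:
        raise ValueError("empty partition")
    return tuple(
        int(math.floor(100.0 * n / union + 0.5))
        for n in (n_culture_only, n_both, n_independent_only)
    )


def partition_from_sets(cultured: set[str], independent: set[str]) -> PartitionResult:
    culture_only = frozenset(cultured - independent)
    both = frozenset(cultured & independent)
    independent_only = frozenset(independent - cultured)
    if not (culture_only or both or independent_only):
        raise ValueError("both detection sets are empty")
    return PartitionResult(
        culture_only,
        both,
        independent_only,
        partition_percentages(len(culture_only), len(both), len(independent_only)),
    )


def partition_otus(independent_counts: np.ndarray, calls: list[CulturedCall]) -> PartitionResult:
    """Three-way partition of all OTUs detected by either method.

    Detection by culture-independent sequencing is count >= 1; detection by
    culture is the cultured call.
    """
    independent_counts = np.asarray(independent_counts)
    if len(independent_counts) != len(calls):
        raise ValueError("independent_counts and calls must be aligned")
    independent = {c.otu_id for c, n in zip(calls, independent_counts) if n >= 1}
    cultured = {c.otu_id for c in calls if c.cultured}
    return partition_from_sets(cultured, independent)


def rank_abundance(
    independent_counts: np.ndarray, calls: list[CulturedCall]
) -> list[RankAbundanceRecord]:
    """OTUs observed culture-independently, ranked by decreasing abundance.

    Ties are broken by OTU id (lexicographic) so ranks are deterministic.
    """
    independent_counts = np.asarray(independent_counts)
    total = independent_counts.sum()
    if total < 1:
        raise ValueError("need at least one observed OTU")
    entries = [
        (c.otu_id, n / total, c.cultured)
        for c, n in zip(calls, independent_counts)
        if n >= 1
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return [
        RankAbundanceRecord(otu_id, rank, float(relab), cultured)
        for rank, (otu_id, relab, cultured) in enumerate(entries, start=1)
    ]


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement (multivariate hypergeometric)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total reads {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def depth_effect_curve(
    independent_counts: np.ndarray,
    calls: list[CulturedCall],
    depths: list[int],
    n_reps: int = 10,
    seed: int = 0,
) -> dict[int, float]:
    """Mean proportion cultured (threshold 0) after rarefying the fecal sample.

    The cultured calls stay fixed; only the culture-independent observation is
    rarefied.  Deeper sequencing reveals more of the rare tail, which is where
    uncultured OTUs concentrate, so the proportion typically falls with depth.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for depth in depths:
        props = []
        for _ in range(n_reps):
            sub = rarefy(independent_counts, depth, rng)
            p, _ = proportion_cultured(sub, calls, 0.0)
            props.append(p)
        out[int(depth)] = float(np.mean(props))
    return out
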