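"""Media recommendation for a target taxon, and isolate novelty screening.

Two questions from the targeted-isolation workflow:

* Which culture conditions enrich a taxon of interest (e.g. the family
  Lachnospiraceae)?  Answered by ranking plate pools by the summed relative
  abundance of OTUs whose lineage matches the taxon.
* Which isolates are putatively novel?  Answered by pairwise global 16S
  identity against a reference collection: an isolate whose best hit falls
  below the identity threshold (default 97 %, the OTU-definition cutoff) is
  flagged novel.  Note this is a pure sequence-identity screen, not a
  taxonomic-classifier confidence call.

The aligner is a deterministic Needleman–Wunsch with linear gap penalties;
identity is computed over alignment columns after trimming terminal-gap
columns, appropriate for near-fully-overlapping 16S reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AnalysisConfig, ConditionSpec, OtuTable, SampleMetadata

__all__ = [
    "MediaRecommendation",
    "IsolateReport",
    "taxon_matches",
    "media_rank_for_taxon",
    "global_align",
    "global_align_identity",
    "classify_isolates",
]


@dataclass
class MediaRecommendation:
    taxon: str
    ranked: list[tuple[ConditionSpec, float]]  # non-increasing relative abundance


@dataclass
class IsolateReport:
    isolate_id: str
    best_reference_id: str
    identity: float
    novel: bool
    alignment_length: int


# ---------------------------------------------------------------------------
# Taxon matching on Greengenes-style lineages
# ---------------------------------------------------------------------------

_RANK_PREFIX = re.compile(r"^[a-z]__", re.IGNORECASE)


def _lineage_fields(lineage: str) -> list[str]:
    return [_RANK_PREFIX.sub("", part.strip()) for part in lineage.split(";")]


def taxon_matches(lineage: str, taxon: str) -> bool:
    """Case-insensitive match of ``taxon`` against whole rank fields.

    Matching only at rank boundaries avoids accidental substring hits (e.g.
    "Clostridium" must not match "Lachnoclostridium").
    """
    t = taxon.strip().lower()
    return any(field.lower() == t for field in _lineage_fields(lineage))


def media_rank_for_taxon(
    table: OtuTable,
    metadata: list[SampleMetadata],
    taxon: str,
    donor: str | None = None,
) -> MediaRecommendation:
    """Rank culture conditions by the target taxon's plate-pool abundance.

    Per plate pool, the target abundance is the summed relative abundance of
    lineage-matching OTUs.  With ``donor=None`` the per-condition mean across
    donors is ranked; ties break lexicographically by (medium, atmosphere).
    """
    if not table.taxonomy:
        raise ValueError("table has no taxonomy annotations")
    match_idx = [
        j
        for j, otu in enumerate(table.otu_ids)
        if otu in table.taxonomy and taxon_matches(table.taxonomy[otu], taxon)
    ]
    if not match_idx:
        raise ValueError(f"taxon {taxon!r} matches no OTU lineage")
    per_condition: dict[ConditionSpec, list[float]] = {}
    for m in metadata:
        if m.role != "plate_pool" or m.storage != "fresh":
            continue
        if donor is not None and m.donor != donor:
            continue
        counts = table.counts_for(m.sample_id)
        total = counts.sum()
        frac = float(counts[match_idx].sum() / total) if total > 0 else 0.0
        per_condition.setdefault(m.condition, []).append(frac)
    if not per_condition:
        raise ValueError("no plate-pool samples to rank")
    ranked = [(cond, float(np.mean(v))) for cond, v in per_condition.items()]
    ranked.sort(key=lambda e: (-e[1], e[0].medium, e[0].atmosphere))
    return MediaRecommendation(taxon, ranked)


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def bases_match(x: str, y: str) -> bool:
    """Conservative IUPAC comparison: match iff one code's set contains the other's."""
    try:
        sx, sy = _IUPAC_SETS[x], _IUPAC_SETS[y]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None
    return sx <= sy or sy <= sx


_CODES = list(_IUPAC_SETS)
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_MATCH_TABLE = np.array(
    [[bases_match(x, y) for y in _CODES] for x in _CODES], dtype=bool
)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def global_align(
    a: str, b: str, scoring: tuple[int, int, int] = (1, -1, -2)
) -> tuple[str, str, int]:
    """Optimal global alignment (Needleman–Wunsch, linear gaps).

    Returns the aligned strings and the optimal score.  Traceback ties are
    broken deterministically: diagonal, then up (gap in ``b``), then left
    (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    match, mismatch, gap = scoring
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    # substitution scores for every (i, j), via the precomputed IUPAC table
    ai = _encode(a)
    bi = _encode(b)
    sub = np.where(_MATCH_TABLE[ai[:, None], bi[None, :]], match, mismatch).astype(np.int64)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        # candidates ending with diagonal or up moves at each column
        cand = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap)
        # fold in left-gap chains with a running-max trick:
        # H[i, j] = max over k <= j of cand'[k] + gap * (j - k)
        b_vals = np.empty(m + 1, dtype=np.int64)
        b_vals[0] = H[i, 0] - gap * 0
        b_vals[1:] = cand - gap * j_idx
        run = np.maximum.accumulate(b_vals)
        H[i, 1:] = run[1:] + gap * j_idx
    # traceback, preferring diagonal, then up, then left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(H[n, m])


def global_align_identity(
    a: str, b: str, scoring: tuple[int, int, int] = (1, -1, -2)
) -> tuple[float, int]:
    """Percent identity of the optimal global alignment.

    Identity = matching columns / alignment columns, counted after trimming
    terminal-gap columns (overhangs do not penalize near-fully-overlapping
    sequences).  Returns (identity, alignment_length).
    """
    aln_a, aln_b, _ = global_align(a, b, scoring)
    cols = [(x, y) for x, y in zip(aln_a, aln_b)]
    start = 0
    end = len(cols)
    while start < end and ("-" in cols[start]):
        start += 1
    while end > start and ("-" in cols[end - 1]):
        end -= 1
    core = cols[start:end]
    if not core:
        return 0.0, 0
    matches = sum(1 for x, y in core if x != "-" and y != "-" and bases_match(x, y))
    return matches / len(core), len(core)


def classify_isolates(
    isolates: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    config: AnalysisConfig | None = None,
) -> list[IsolateReport]:
    """Screen isolates against a reference collection by best pairwise identity.

    Each isolate is globally aligned to every reference; the best hit (ties
    -> lexicographically smallest reference id) determines the identity, and
    ``novel`` flags identities below the configured threshold.
    """
    if not isolates or not references:
        raise ValueError("isolates and references must both be non-empty")
    config = config or AnalysisConfig()
    reports: list[IsolateReport] = []
    for iso_id, iso_seq in isolates:
        best: tuple[float, str, int] | None = None
        for ref_id, ref_seq in sorted(references):
            ident, length = global_align_identity(iso_seq, ref_seq)
            if best is None or ident > best[0]:
                best = (ident, ref_id, length)
        ident, ref_id, length = best
        reports.append(
            IsolateReport(
                isolate_id=iso_id,
                best_reference_id=ref_id,
                identity=ident,
                novel=ident < config.identity_threshold,
                alignment_length=length,
            )
        )
    return reports
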