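"""Minimal media sets: which culture conditions suffice to recover everything?

Framed as set cover: the targets are the culturable OTUs observed above an
abundance threshold in the culture-independent sample, and each culture
condition covers the targets it recovered at the cultured-read floor.  Two
solvers are provided: the standard greedy heuristic (scalable, deterministic
tie-breaks) and an exact branch-and-bound that certifies minimum cardinality
on designs of up to ~30 conditions.  OTUs above threshold that no condition
recovered are excluded from the target up front — only *culturable* OTUs can
be covered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .enrichment import CulturedCall
from .io_formats import AnalysisConfig, ConditionSpec, OtuTable, SampleMetadata

__all__ = [
    "CoverInstance",
    "CoverResult",
    "build_cover_instance",
    "greedy_cover",
    "exact_cover",
    "cross_donor_union",
]


@dataclass
class CoverInstance:
    targets: frozenset[str]
    condition_sets: dict[ConditionSpec, frozenset[str]]

    def __post_init__(self) -> None:
        covered = frozenset().union(*self.condition_sets.values()) if self.condition_sets else frozenset()
        if not self.targets <= covered:
            raise ValueError("targets must be a subset of the union of condition sets")


@dataclass
class CoverResult:
    selected: tuple[ConditionSpec, ...]
    method: str
    covered: frozenset[str]
    is_certified_minimum: bool


def build_cover_instance(
    table: OtuTable,
    metadata: list[SampleMetadata],
    calls: list[CulturedCall],
    config: AnalysisConfig,
    donor: str,
    threshold: float = 0.001,
    atmosphere: str | None = None,
) -> CoverInstance:
    """Targets and per-condition recovery sets for one donor.

    Targets = OTUs above ``threshold`` relative abundance in the donor's
    culture-independent sample AND cultured somewhere (per ``calls``).
    ``atmosphere`` optionally restricts the design to one incubation
    atmosphere.
    """
    fecal = [m for m in metadata if m.donor == donor and m.role == "culture_independent"]
    if not fecal:
        raise ValueError(f"donor {donor!r} has no culture-independent sample")
    counts = table.counts_for(fecal[0].sample_id)
    total = counts.sum()
    if total == 0:
        return CoverInstance(frozenset(), {})
    relab = counts / total
    above = {o for o, r in zip(table.otu_ids, relab) if r > threshold}

    call_map = {c.otu_id: c for c in calls}
    condition_sets: dict[ConditionSpec, set[str]] = {}
    for c in calls:
        for medium, atm in c.supporting_conditions:
            if atmosphere is not None and atm != atmosphere:
                continue
            condition_sets.setdefault(ConditionSpec(medium, atm), set())

    cultured_somewhere = set()
    for otu in above:
        c = call_map.get(otu)
        if c is None:
            continue
        conds = [
            (m, a)
            for (m, a) in c.supporting_conditions
            if atmosphere is None or a == atmosphere
        ]
        if conds:
            cultured_somewhere.add(otu)
            for medium, atm in conds:
                condition_sets.setdefault(ConditionSpec(medium, atm), set()).add(otu)

    frozen_sets = {cond: frozenset(s & cultured_somewhere) for cond, s in condition_sets.items()}
    return CoverInstance(frozenset(cultured_somewhere), frozen_sets)


def _check_cover(instance: CoverInstance, selected: Sequence[ConditionSpec]) -> frozenset[str]:
    covered = frozenset().union(*(instance.condition_sets[c] for c in selected)) if selected else frozenset()
    if covered != instance.targets:
        raise AssertionError("cover post-condition violated: covered != targets")
    return covered


def greedy_cover(instance: CoverInstance) -> CoverResult:
    """Standard greedy: take the condition covering most uncovered targets.

    Ties break lexicographically by (medium, atmosphere) so the result is
    bit-reproducible.  Not certified minimum.
    """
    uncovered = set(instance.targets)
    selected: list[ConditionSpec] = []
    conditions = sorted(instance.condition_sets)
    while uncovered:
        best_gain = -1
        best_cond = None
        for c in conditions:
            gain = len(instance.condition_sets[c] & uncovered)
            if gain > best_gain:
                best_gain, best_cond = gain, c
        if best_gain <= 0:
            raise ValueError("infeasible cover instance")
        selected.append(best_cond)
        uncovered -= instance.condition_sets[best_cond]
    covered = _check_cover(instance, selected)
    return CoverResult(tuple(selected), "greedy", covered, False)


def exact_cover(instance: CoverInstance, max_conditions: int = 30) -> CoverResult:
    """Provably minimum-cardinality cover by depth-limited search.

    Conditions are explored in lexicographic order at increasing solution
    size, so the first solution found is both minimum-cardinality and, among
    equal-size covers, the lexicographically smallest selection.  Guarded to
    ``max_conditions`` conditions (exponential worst case beyond that — use
    greedy instead).
    """
    useful = sorted(c for c, s in instance.condition_sets.items() if s & instance.targets)
    if len(instance.condition_sets) > max_conditions:
        raise ValueError(
            f"{len(instance.condition_sets)} conditions exceeds the exact-search guard "
            f"({max_conditions}); use greedy_cover"
        )
    if not instance.targets:
        return CoverResult((), "exact", frozenset(), True)

    sets = [instance.condition_sets[c] for c in useful]
    n = len(useful)
    # suffix unions for pruning: what can still be covered from index i on
    suffix: list[frozenset[str]] = [frozenset()] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] | sets[i]
    max_gain = max((len(s) for s in sets), default=0)
    upper = len(greedy_cover(instance).selected)

    def dfs(start: int, chosen: list[int], covered: frozenset[str], k: int) -> list[int] | None:
        if covered >= instance.targets:
            return list(chosen)
        remaining_slots = k - len(chosen)
        if remaining_slots == 0:
            return None
        missing = instance.targets - covered
        if not missing <= suffix[start]:
            return None
        if len(missing) > remaining_slots * max_gain:
            return None
        for i in range(start, n):
            if not (sets[i] & missing):
                continue
            chosen.append(i)
            hit = dfs(i + 1, chosen, covered | sets[i], k)
            if hit is not None:
                return hit
            chosen.pop()
        return None

    for k in range(1, upper + 1):
        hit = dfs(0, [], frozenset(), k)
        if hit is not None:
            selected = tuple(useful[i] for i in hit)
            covered = _check_cover(instance, selected)
            return CoverResult(selected, "exact", covered, True)
    raise ValueError("infeasible cover instance")  # pragma: no cover - guarded by invariant


def cross_donor_union(
    results: Mapping[str, CoverResult], atmosphere: str | None = None
) -> tuple[frozenset[ConditionSpec], int]:
    """Union of selected conditions across donors (optionally one atmosphere).

    Measures condition redundancy: a large union relative to any single
    donor's cover means the required media differ between individuals.
    """
    if not results:
        raise ValueError("need at least one donor result")
    union: set[ConditionSpec] = set()
    for res in results.values():
        for cond in res.selected:
            if atmosphere is None or cond.atmosphere == atmosphere:
                union.add(cond)
    return frozenset(union), len(union)
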