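import numpy as np
import pytest

from cultenrich import enrichment as en
from cultenrich.io_formats import AnalysisConfig, OtuTable, SampleMetadata


def test_cultured_call_threshold_boundary(tiny_table, tiny_metadata, config):
    calls = {c.otu_id: c for c in en.call_cultured(tiny_table, tiny_metadata, config, "D1")}
    # 9 reads on a plate is below the 10-read floor
    assert not calls["O3"].cultured
    # exactly 10 reads on exactly one plate qualifies
    assert calls["O2"].cultured
    assert calls["O2"].supporting_conditions == [("M2", "aerobic")]
    assert calls["O1"].supporting_conditions == [("M1", "anaerobic")]
    assert calls["O4"].cultured


def test_cultured_call_with_floor_one(tiny_table, tiny_metadata):
    cfg = AnalysisConfig(min_cultured_reads=1)
    calls = {c.otu_id: c for c in en.call_cultured(tiny_table, tiny_metadata, cfg, "D1")}
    assert calls["O3"].cultured  # present anywhere on plates now counts


def test_call_cultured_unknown_donor(tiny_table, tiny_metadata, config):
    with pytest.raises(ValueError, match="absent"):
        en.call_cultured(tiny_table, tiny_metadata, config, "D9")


def test_controls_are_excluded(tiny_table, config):
    metadata = [
        SampleMetadata("F", "culture_independent", "D1", "", "none", "fresh"),
        SampleMetadata("P1", "plate_pool", "D1", "M1", "anaerobic", "fresh"),
        SampleMetadata("P2", "no_growth_control", "D1", "M2", "aerobic", "fresh"),
    ]
    calls = {c.otu_id: c for c in en.call_cultured(tiny_table, metadata, config, "D1")}
    assert not calls["O2"].cultured  # its 10 reads sit on the control plate


def _calls(flags):
    return [
        en.CulturedCall(f"O{i + 1}", bool(f), [("M1", "anaerobic")] if f else [], 0.1)
        for i, f in enumerate(flags)
    ]


@pytest.mark.parametrize(
    "threshold,flags,expected",
    [
        # relabunds are 0.9 / 0.05 / 0.05
        (0.06, [1, 0, 0], (1.0, 1)),
        (0.04, [1, 1, 0], (2 / 3, 3)),
        (0.0, [1, 1, 1], (1.0, 3)),
    ],
)
def test_proportion_cultured_hand_computed(threshold, flags, expected):
    counts = np.array([900, 50, 50])
    prop, n = en.proportion_cultured(counts, _calls(flags), threshold)
    assert (prop, n) == (pytest.approx(expected[0]), expected[1])


def test_proportion_cultured_empty_consideration_errors():
    with pytest.raises(ValueError, match="no OTUs above threshold"):
        en.proportion_cultured(np.array([10, 10]), _calls([1, 1]), 0.9)


def test_partition_sets_and_percentages(tiny_table, tiny_metadata, config):
    calls = en.call_cultured(tiny_table, tiny_metadata, config, "D1")
    part = en.partition_otus(tiny_table.counts_for("F"), calls)
    assert part.culture_only == frozenset({"O4"})
    assert part.both == frozenset({"O1", "O2"})
    assert part.independent_only == frozenset({"O3"})
    assert part.percentages == (25, 50, 25)
    # disjoint and exhaustive
    assert part.union_size == 4


def test_partition_percentage_rounding():
    assert en.partition_percentages(1, 1, 1) == (33, 33, 33)  # sums to 99
    assert en.partition_percentages(0, 5, 0) == (0, 100, 0)
    with pytest.raises(ValueError):
        en.partition_percentages(0, 0, 0)


def test_rank_abundance_ordering_and_ties():
    counts = np.array([50, 100, 50, 0])
    calls = _calls([1, 1, 0, 0])
    recs = en.rank_abundance(counts, calls)
    assert [r.otu_id for r in recs] == ["O2", "O1", "O3"]  # tie O1/O3 lexicographic
    assert [r.rank for r in recs] == [1, 2, 3]
    assert recs[0].relabund == pytest.approx(0.5)
    # uncultured-but-abundant filter, as used for the rank-abundance plot
    assert [r.otu_id for r in recs if not r.cultured and r.relabund > 0.001] == ["O3"]
    single = en.rank_abundance(np.array([7]), _calls([1]))
    assert (single[0].rank, single[0].relabund) == (1, 1.0)


@pytest.mark.parametrize("scale", [1, 2, 7, 50])
def test_proportion_invariant_under_plate_scaling(scale, tiny_table, tiny_metadata, config):
    # the cultured call depends only on the >= floor predicate, so scaling all
    # plate counts by a common factor can only keep or add calls; with floor 1
    # it is exactly invariant
    cfg = AnalysisConfig(min_cultured_reads=1)
    scaled = OtuTable(
        tiny_table.sample_ids,
        tiny_table.otu_ids,
        np.vstack([tiny_table.counts[0], tiny_table.counts[1:] * scale]),
    )
    base = en.call_cultured(tiny_table, tiny_metadata, cfg, "D1")
    after = en.call_cultured(scaled, tiny_metadata, cfg, "D1")
    assert [c.cultured for c in base] == [c.cultured for c in after]
    fecal = tiny_table.counts_for("F")
    assert en.proportion_cultured(fecal, base, 0.0) == en.proportion_cultured(fecal, after, 0.0)


def _brute_force(table, metadata, donor, min_reads):
    """Independent dict-based recomputation of calls and partition."""
    cultured = set()
    independent = set()
    for m in metadata:
        row = table.counts_for(m.sample_id)
        for otu, n in zip(table.otu_ids, row):
            if m.role == "plate_pool" and m.donor == donor and n >= min_reads:
                cultured.add(otu)
            if m.role == "culture_independent" and m.donor == donor and n >= 1:
                independent.add(otu)
    return cultured, independent


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_on_small_tables(seed, config):
    rng = np.random.default_rng(seed)
    n_otus = rng.integers(2, 11)
    conds = [("M1", "anaerobic"), ("M2", "anaerobic"), ("M3", "aerobic"), ("M4", "aerobic")]
    n_cond = rng.integers(1, 5)
    counts = rng.integers(0, 30, size=(1 + n_cond, n_otus))
    sample_ids = ["F"] + [f"P{i}" for i in range(n_cond)]
    metadata = [SampleMetadata("F", "culture_independent", "D1", "", "none", "fresh")] + [
        SampleMetadata(f"P{i}", "plate_pool", "D1", conds[i][0], conds[i][1], "fresh")
        for i in range(n_cond)
    ]
    table = OtuTable(sample_ids, [f"O{j}" for j in range(n_otus)], counts)
    calls = en.call_cultured(table, metadata, config, "D1")
    cultured, independent = _brute_force(table, metadata, "D1", config.min_cultured_reads)
    assert {c.otu_id for c in calls if c.cultured} == cultured
    if cultured or independent:
        part = en.partition_otus(table.counts_for("F"), calls)
        assert set(part.culture_only) == cultured - independent
        assert set(part.both) == cultured & independent
        assert set(part.independent_only) == independent - cultured


def test_culture_only_never_contains_unculturable_truth(small_experiment, config):
    exp = small_experiment
    calls = en.call_cultured(exp.table, exp.metadata, config, "D1")
    part = en.partition_otus(exp.table.counts_for("D1.fecal"), calls)
    unculturable = set(exp.truth.community.otu_ids) - set(exp.truth.truly_culturable_ids())
    assert not (set(part.culture_only) & unculturable)


def test_depth_curve_identity_at_full_depth(tiny_table, tiny_metadata, config):
    calls = en.call_cultured(tiny_table, tiny_metadata, config, "D1")
    fecal = tiny_table.counts_for("F")
    full = int(fecal.sum())
    exact, _ = en.proportion_cultured(fecal, calls, 0.0)
    curve = en.depth_effect_curve(fecal, calls, [full], n_reps=5, seed=1)
    assert curve[full] == pytest.approx(exact)
    with pytest.raises(ValueError, match="exceeds total"):
        en.depth_effect_curve(fecal, calls, [full + 1], n_reps=2, seed=1)


def test_depth_one_gives_degenerate_proportions(tiny_table, tiny_metadata, config):
    calls = en.call_cultured(tiny_table, tiny_metadata, config, "D1")
    fecal = tiny_table.counts_for("F")
    rng = np.random.default_rng(0)
    for _ in range(10):
        sub = en.rarefy(fecal, 1, rng)
        p, n = en.proportion_cultured(sub, calls, 0.0)
        assert n == 1 and p in (0.0, 1.0)
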