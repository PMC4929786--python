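import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cultenrich import synthetic as sy
from cultenrich.community_compare import bray_curtis
from cultenrich.io_formats import ConditionSpec


CONDS = sy.default_conditions(n_media=4)


def test_community_is_normalized_and_deterministic():
    a = sy.generate_community(500, seed=1, sigma=2.0)
    b = sy.generate_community(500, seed=1, sigma=2.0)
    assert np.array_equal(a.true_abundance, b.true_abundance)
    assert abs(a.true_abundance.sum() - 1.0) < 1e-9
    assert np.all(np.diff(a.true_abundance) <= 0)  # ids assigned in rank order
    assert a.true_abundance[0] > np.median(a.true_abundance)


def test_community_single_otu_and_bad_params():
    one = sy.generate_community(1, seed=0)
    assert one.true_abundance.tolist() == [1.0]
    with pytest.raises(ValueError):
        sy.generate_community(0)
    with pytest.raises(ValueError):
        sy.generate_community(5, sigma=-1)
    with pytest.raises(ValueError):
        sy.generate_community(5, model="weibull")


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_lognormal_community_is_long_tailed(seed):
    # at sigma=2 the top decile of OTUs carries most of the community mass
    c = sy.generate_community(500, seed=seed, sigma=2.0)
    top = np.sort(c.true_abundance)[::-1][:50].sum()
    assert top > 0.5


@pytest.mark.parametrize("frac,expected", [(0.0, 0), (0.5, 50), (1.0, 100)])
def test_culturability_exact_count_contract(frac, expected):
    c = sy.generate_community(100, seed=7)
    m = sy.generate_culturability(c, CONDS, frac, 4.0, seed=8)
    assert int(m.culturable_mask.sum()) == expected


def test_culturability_single_condition_full_coverage():
    c = sy.generate_community(30, seed=7)
    m = sy.generate_culturability(c, [ConditionSpec("M01", "anaerobic")], 1.0, 5.0, seed=8)
    assert np.all(m.growth_factor[0] > 0)


def test_some_growth_factors_amplify():
    c = sy.generate_community(200, seed=7)
    m = sy.generate_culturability(c, CONDS, 0.8, 2.0, seed=8)
    pos = m.growth_factor[m.growth_factor > 0]
    assert (pos > 1).any() and (pos < 1).any()


def test_sequencing_counts_sum_to_depth():
    c = sy.generate_community(50, seed=1)
    assert sy.simulate_sequencing(c.true_abundance, 0, seed=1).sum() == 0
    draw = sy.simulate_sequencing(c.true_abundance, 12345, seed=1)
    assert draw.sum() == 12345
    assert np.array_equal(draw, sy.simulate_sequencing(c.true_abundance, 12345, seed=1))
    single = sy.simulate_sequencing(np.array([1.0]), 1000, seed=2)
    assert single.tolist() == [1000]


def test_sequencing_matches_binomial_scale():
    # two equal OTUs at depth 1e6: each count within 3 sigma of n/2
    draw = sy.simulate_sequencing(np.array([0.5, 0.5]), 10**6, seed=3)
    sigma = np.sqrt(10**6 * 0.25)
    assert abs(draw[0] - 5 * 10**5) < 3 * sigma


def test_plate_pool_respects_growth_zeros():
    c = sy.generate_community(10, seed=4)
    growth = np.ones(10)
    growth[3] = 0.0
    for seed in range(5):
        counts = sy.simulate_plate_pool(c, growth, 5000, seed=seed)
        assert counts[3] == 0
        assert counts.sum() == 5000


def test_plate_pool_uniform_growth_equals_community():
    c = sy.generate_community(10, seed=4)
    assert np.allclose(sy.plate_composition(c, np.full(10, 2.5)), c.true_abundance)


def test_plate_pool_selective_enrichment_of_rare_otu():
    c = sy.CommunityTruth(["a", "b"], np.array([0.99, 0.01]))
    counts = sy.simulate_plate_pool(c, np.array([0.0, 1.0]), 1000, seed=1)
    assert counts.tolist() == [0, 1000]


def test_plate_pool_no_growth_errors_without_background():
    c = sy.generate_community(5, seed=1)
    with pytest.raises(sy.NoGrowthError, match="no growth"):
        sy.simulate_plate_pool(c, np.zeros(5), 100, seed=1)
    # dead-DNA background rescues it with the fecal profile
    counts = sy.simulate_plate_pool(c, np.zeros(5), 100, seed=1, background_rate=0.02)
    assert counts.sum() == 100


def test_no_growth_control_resembles_fecal_not_selective_plate():
    c = sy.generate_community(100, seed=10)
    fecal = sy.simulate_sequencing(c.true_abundance, 50_000, seed=11)
    control = sy.simulate_no_growth_control(c, 50_000, seed=12)
    growth = np.zeros(100)
    growth[60:70] = 5.0  # strongly selective plate
    plate = sy.simulate_plate_pool(c, growth, 50_000, seed=13)
    assert bray_curtis(control, plate) > bray_curtis(control, fecal)
    assert sy.simulate_no_growth_control(c, 0, seed=1).sum() == 0


def test_perturbation_magnitude_zero_and_one():
    c = sy.generate_community(80, seed=20)
    m = sy.generate_culturability(c, CONDS, 0.8, 3.0, seed=21)
    same = sy.apply_perturbation(m, sy.PerturbationSpec("frozen", 0.0, 1))
    assert np.array_equal(same.growth_factor, m.growth_factor)
    killed = sy.apply_perturbation(m, sy.PerturbationSpec("frozen", 1.0, 1))
    assert not (killed.growth_factor > 0).any()
    damped = sy.apply_perturbation(m, sy.PerturbationSpec("aerobic_exposed", 1.0, 1))
    pos = m.growth_factor > 0
    assert np.allclose(damped.growth_factor[pos], 0.1 * m.growth_factor[pos])


def test_perturbation_shifts_communities_monotonically():
    c = sy.generate_community(200, seed=30)
    m = sy.generate_culturability(c, CONDS, 0.8, 3.0, seed=31)
    fresh = sy.build_experiment(c, m, donor="D1", plate_depth=100_000, seed=32,
                                include_independent=False)
    bcs = []
    for mag in (0.0, 0.3, 0.7):
        pert = sy.apply_perturbation(m, sy.PerturbationSpec("frozen", mag, 99))
        frozen = sy.build_experiment(c, pert, donor="D1", plate_depth=100_000, seed=33,
                                     storage="frozen", include_independent=False)
        pair = [
            bray_curtis(fresh.table.counts[i], frozen.table.counts[i])
            for i in range(len(CONDS))
        ]
        bcs.append(np.mean(pair))
    assert bcs[0] < bcs[1] < bcs[2]


def test_isolates_divergence_contract():
    refs = sy.generate_reference_sequences(3, 1000, seed=40)
    exact = sy.generate_isolate_sequences(refs, 4, 0.0, seed=41)
    for iso_id, seq, parent, ident in exact:
        assert ident == 1.0
        assert seq == dict(refs)[parent]
    mutated = sy.generate_isolate_sequences(refs, 4, 0.05, seed=42)
    for _, seq, parent, ident in mutated:
        parent_seq = dict(refs)[parent]
        n_diff = sum(a != b for a, b in zip(seq, parent_seq))
        assert n_diff == 50
        assert ident == pytest.approx(0.95)
    assert mutated == sy.generate_isolate_sequences(refs, 4, 0.05, seed=42)


def test_build_experiment_full_design():
    c = sy.generate_community(60, seed=50)
    conds = sy.default_conditions()  # 33 media x 2 atmospheres
    m = sy.generate_culturability(c, conds, 0.9, 2.0, seed=51)
    exp = sy.build_experiment(c, m, donor="HV1", independent_depth=5000,
                              plate_depth=2000, seed=52)
    assert exp.table.n_samples == 67  # 66 plate pools + 1 fecal
    assert exp.table.otu_ids == c.otu_ids
    assert exp.truth.community is c
    roles = {md.role for md in exp.metadata}
    assert roles == {"culture_independent", "plate_pool"}
    assert all(exp.table.sample_totals()[1:] == 2000)


def test_build_experiment_byte_identical_for_fixed_seed(tmp_path):
    from cultenrich.io_formats import write_otu_table

    c = sy.generate_community(40, seed=60)
    m = sy.generate_culturability(c, CONDS, 0.8, 3.0, seed=61)
    for name in ("a", "b"):
        exp = sy.build_experiment(c, m, donor="D1", independent_depth=3000,
                                  plate_depth=1000, seed=62)
        write_otu_table(exp.table, tmp_path / name)
    assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()


@given(depth=st.integers(0, 2000), seed=st.integers(0, 10**6))
@settings(max_examples=40)
def test_count_conservation_property(depth, seed):
    c = sy.generate_community(30, seed=5)
    growth = np.ones(30)
    assert sy.simulate_plate_pool(c, growth, depth, seed=seed).sum() == depth


def test_zero_growth_otus_never_on_plates(small_experiment):
    exp = small_experiment
    never = ~exp.truth.culturability.culturable_mask
    plate_rows = [i for i, m in enumerate(exp.metadata) if m.role == "plate_pool"]
    assert exp.table.counts[np.ix_(plate_rows, np.flatnonzero(never))].sum() == 0
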