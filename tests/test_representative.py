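import numpy as np
import pytest

from oligorep import (AnalogMember, AnalogSet, ReactionSystem,
                      as_analog_set, binding_constant, derive_rs,
                      duplex_delta_g, iterative_rs, merge_pair,
                      pearson_profile, rs_concentration, select_cs,
                      solve_competition, total_yield, wc_complement)
from oligorep.examples import three_analog_example, two_analog_example
from conftest import random_seq


def pair_set(a, b, ca=1.0, cb=1.0):
    return AnalogSet(members=(AnalogMember("a", a, ca), AnalogMember("b", b, cb)))


def test_identical_analogs_yield_the_perfect_complement(params, cfg):
    seq = "ACGTTGCAGA"
    cs, state = select_cs(pair_set(seq, seq), 1000, params, cfg)
    assert cs == wc_complement(seq)
    assert derive_rs(cs) == seq
    assert total_yield(state) == pytest.approx(2.0, abs=1e-3)


def test_rs_concentration_recovers_the_combined_analog_amount(params, cfg):
    """Two identical 1-unit analogs bind ~2 units of CS, so the equivalent
    RS concentration is ~2 units."""
    seq = "ACGTTGCAGA"
    cs, state = select_cs(pair_set(seq, seq), 1000, params, cfg)
    bound = float(np.sum(state.duplex))
    conc = rs_concentration(cs, state.system.candidate_total, bound, params, cfg)
    assert conc == pytest.approx(2.0, rel=1e-3)


def test_rs_concentration_limits_and_self_consistency(params, cfg):
    cs = "TCCGGCGGTG"
    assert rs_concentration(cs, 2.0, 0.0, params, cfg) == 0.0
    with pytest.raises(ValueError):
        rs_concentration(cs, 2.0, 2.0, params, cfg)
    # re-running the single-strand equilibrium at the solved concentration
    # reproduces the requested bound amount
    amount = 1.7
    conc = rs_concentration(cs, 2.0, amount, params, cfg)
    rs = derive_rs(cs)
    k = binding_constant(duplex_delta_g(rs, cs, params, cfg), cfg)
    state = solve_competition(ReactionSystem(
        analog_totals=np.array([conc]), binding_constants=np.array([k]),
        candidate_total=2.0))
    assert float(state.duplex[0]) == pytest.approx(amount, rel=1e-10)


def test_cs_beats_both_anti_analogs_on_the_bundled_pair(params, cfg):
    """The CS trades a little per-analog affinity for the best summed yield,
    landing closer to the perfect-hybridization corner than either
    anti-analog."""
    pair = two_analog_example()
    cs, state = select_cs(pair, 1000, params, cfg)
    perfect = pair.concentrations
    cs_dist = np.linalg.norm(state.duplex - perfect)
    for seq in pair.sequences:
        anti = wc_complement(seq)
        dg = [duplex_delta_g(s, anti, params, cfg) for s in pair.sequences]
        anti_state = solve_competition(ReactionSystem(
            analog_totals=perfect, binding_constants=binding_constant(dg, cfg)))
        assert total_yield(state) > total_yield(anti_state)
        assert cs_dist < np.linalg.norm(anti_state.duplex - perfect)


def test_rs_profile_sits_between_the_analogs(params, cfg):
    pair = two_analog_example()
    cs, _ = select_cs(pair, 1000, params, cfg)
    rs = derive_rs(cs)
    a, b = pair.sequences
    r_ab = pearson_profile(a, b, params, cfg)
    assert pearson_profile(rs, a, params, cfg) > r_ab
    assert pearson_profile(rs, b, params, cfg) > r_ab


def test_pooled_argmax_matches_exhaustive_search_at_n6(params, cfg, rng):
    """The top-1000 shortlist heuristic finds the same CS as scoring every
    candidate in the 4**6 space (spot check; the wide version runs in the
    acceptance suite)."""
    for _ in range(10):
        a = random_seq(rng, 6)
        b = list(a)
        for p in rng.permutation(6)[:2]:
            b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
        analogs = pair_set(a, "".join(b))
        cs_pool, _ = select_cs(analogs, 1000, params, cfg)
        cs_full, _ = select_cs(analogs, 4 ** 6, params, cfg)
        assert cs_pool == cs_full


def test_two_analog_iteration_equals_direct_selection(params, cfg):
    pair = two_analog_example()
    cs, state = select_cs(pair, 1000, params, cfg)
    result = iterative_rs(pair, 1000, 1000, params, cfg)
    assert result.cs == cs
    assert result.rs == derive_rs(cs)
    assert len(result.merge_tree) == 1
    assert result.total_yield == pytest.approx(total_yield(state), rel=1e-8)


def test_merge_pair_names_and_concentration(params, cfg):
    three = three_analog_example()
    merged, step = merge_pair(three, "Analog 2", "Analog 3", 1000, params, cfg)
    assert len(merged) == 2
    assert "Analog 2/Analog 3" in merged.names
    assert step.rs_concentration > 0
    assert step.rs == wc_complement(step.cs)
    with pytest.raises(ValueError):
        merge_pair(three, "Analog 2", "Analog 2", 1000, params, cfg)


def test_iterative_rs_is_order_invariant(params, cfg):
    three = three_analog_example()
    shuffled = AnalogSet(members=three.members[::-1], origin=three.origin)
    r1 = iterative_rs(three, 1000, 1000, params, cfg)
    r2 = iterative_rs(shuffled, 1000, 1000, params, cfg)
    assert r1.cs == r2.cs and r1.rs == r2.rs
    assert r1.rs_concentration == pytest.approx(r2.rs_concentration, rel=1e-12)


def test_iterative_rs_merges_the_closest_pair_first(params, cfg):
    from oligorep import closeness_matrix
    three = three_analog_example()
    cm = closeness_matrix(three.sequences, three.names, 1000, params, cfg)
    arr = cm.to_numpy().astype(float)
    np.fill_diagonal(arr, -1)
    i, j = np.unravel_index(np.argmax(arr), arr.shape)
    expected = {cm.index[i], cm.index[j]}
    result = iterative_rs(three, 1000, 1000, params, cfg)
    assert set(result.merge_tree[0].merged) == expected
    assert result.merge_tree[0].closeness == arr[i, j]


def test_final_yields_are_consistent_with_the_equilibrium_module(params, cfg):
    three = three_analog_example()
    result = iterative_rs(three, 1000, 1000, params, cfg)
    dg = [duplex_delta_g(s, result.cs, params, cfg) for s in three.sequences]
    state = solve_competition(ReactionSystem(
        analog_totals=three.concentrations,
        binding_constants=binding_constant(dg, cfg)))
    np.testing.assert_allclose(result.per_analog_yield, state.yields,
                               rtol=1e-8)
    assert result.total_yield == pytest.approx(total_yield(state), rel=1e-8)


def test_concentration_weighting_flows_into_the_selection(params, cfg):
    """Concentrations enter the CS choice through the equilibrium: a
    single-analog set degenerates to the perfect anti-strand, and in a
    strongly biased mixture the selected CS still binds *both* analogs
    nearly fully -- out-yielding the dominant analog's own anti-strand,
    which starves the minority species."""
    pair = two_analog_example()
    a, b = pair.sequences
    single = AnalogSet(members=(AnalogMember("a", a, 1.0),))
    cs_single, _ = select_cs(single, 1000, params, cfg)
    assert cs_single == wc_complement(a)

    biased = pair_set(a, b, 1.9998, 0.0002)
    cs_biased, state = select_cs(biased, 1000, params, cfg)
    assert np.all(state.yields > 0.999)
    dg = [duplex_delta_g(s, wc_complement(a), params, cfg) for s in (a, b)]
    anti_state = solve_competition(ReactionSystem(
        analog_totals=biased.concentrations,
        binding_constants=binding_constant(dg, cfg)))
    assert total_yield(state) > total_yield(anti_state)


def test_as_analog_set_coercions():
    s = as_analog_set(["ACGTACGT", ("x", "ACGTTCGT", 2.0)])
    assert s.names == ["seq1", "x"]
    assert s.concentrations[1] == 2.0
    with pytest.raises(ValueError):
        as_analog_set([])
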