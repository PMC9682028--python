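"""Candidate pairing, Spearman thresholding and network assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import (
    ExpressionMatrix,
    InteractionTable,
    build_state_network,
    candidate_pairs,
    degree_table,
    extract_axes,
    generate_expression,
    generate_interactions,
    spearman_rho,
)
from cernet.containers import LNCRNA, MRNA
from conftest import brute_force_candidates, make_expression, make_network


def table(side, pairs):
    return InteractionTable.from_pairs(side, pairs)


class TestCandidatePairs:
    def test_full_overlap_in_minimal_universe(self):
        """Four shared miRNAs out of a 4-miRNA universe: overlap is forced,
        so the hypergeometric tail is exactly 1."""
        lnc = table(LNCRNA, [("L", f"m{i}") for i in range(4)])
        mrna = table(MRNA, [("G", f"m{i}") for i in range(4)])
        (pair,) = candidate_pairs(lnc, mrna, min_shared=4)
        assert pair.shared_count == 4
        assert pair.p_shared == pytest.approx(1.0)

    def test_three_shared_is_not_more_than_three(self):
        lnc = table(LNCRNA, [("L", f"m{i}") for i in range(3)])
        mrna = table(MRNA, [("G", f"m{i}") for i in range(3)])
        assert candidate_pairs(lnc, mrna, min_shared=4) == []

    def test_disjoint_targets_no_pair(self):
        lnc = table(LNCRNA, [("L", "m1"), ("L", "m2"), ("L", "m3"), ("L", "m4")])
        mrna = table(MRNA, [("G", "m5"), ("G", "m6"), ("G", "m7"), ("G", "m8")])
        assert candidate_pairs(lnc, mrna, min_shared=1) == []

    def test_min_shared_below_one_rejected(self):
        lnc = table(LNCRNA, [("L", "m1")])
        with pytest.raises(ValueError):
            candidate_pairs(lnc, lnc, min_shared=0)

    def test_empty_table_yields_empty_result(self, toy_tables):
        lnc, _ = toy_tables
        empty = InteractionTable(side=MRNA, edges=frozenset())
        assert candidate_pairs(lnc, empty) == []

    def test_matches_brute_force_on_synthetic_tables(self, small_config):
        lnc, mrna, _ = generate_interactions(small_config)
        oracle = brute_force_candidates(lnc, mrna, 4)
        got = {(c.lncrna, c.mrna): c.shared_mirnas for c in candidate_pairs(lnc, mrna, 4)}
        assert got == oracle

    def test_p_shared_matches_hypergeometric_tail(self, toy_tables):
        lnc, mrna = toy_tables
        for c in candidate_pairs(lnc, mrna, min_shared=1):
            n_l = len(lnc.targets_of(c.lncrna))
            n_m = len(mrna.targets_of(c.mrna))
            universe = len(lnc.mirnas | mrna.mirnas)
            expected = stats.hypergeom.sf(c.shared_count - 1, universe, n_m, n_l)
            assert c.p_shared == pytest.approx(float(expected), abs=1e-12)


class TestSpearman:
    def test_identical_ranks(self):
        assert spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_rank_difference_formula(self):
        """Tie-free case agrees with 1 - 6*sum(d^2)/(n(n^2-1))."""
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        assert spearman_rho(x, y) == pytest.approx(1 - 6 * d2 / (5 * 24), abs=1e-12)

    def test_constant_vector_is_nan(self):
        assert math.isnan(spearman_rho([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]))

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(8), rng.random(8)
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x))
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestStateNetwork:
    def test_planted_perfect_pair_present(self):
        from cernet import SimulationConfig
        cfg = SimulationConfig(n_planted_pairs=1, rho_target=1.0,
                               background_density=0.0, de_fraction=0.0, seed=2)
        lnc, mrna, truth = generate_interactions(cfg)
        expr = generate_expression(cfg, truth)
        ((l, g, state),) = truth.planted_pairs
        net = build_state_network(candidate_pairs(lnc, mrna), expr, state)
        assert (l, g) in net.edges
        assert net.edges[(l, g)].rho == pytest.approx(1.0)

    def test_below_cutoff_excluded(self, toy_tables):
        lnc = table(LNCRNA, [("L", f"m{i}") for i in range(4)])
        mrna = table(MRNA, [("G", f"m{i}") for i in range(4)])
        cands = candidate_pairs(lnc, mrna)
        # ranks (1,2,3,4,5) vs (3,1,2,4,5): sum d^2 = 6 -> rho = 0.7
        expr = make_expression({"L": [1, 2, 3, 4, 5], "G": [3, 1, 2, 4, 5]},
                               ["control"] * 5)
        net = build_state_network(cands, expr, "control", rho_min=0.9)
        assert net.n_edges() == 0

    def test_constant_profile_never_passes(self):
        lnc = table(LNCRNA, [("L", f"m{i}") for i in range(4)])
        mrna = table(MRNA, [("G", f"m{i}") for i in range(4)])
        expr = make_expression({"L": [2, 2, 2, 2, 2], "G": [1, 2, 3, 4, 5]},
                               ["control"] * 5)
        net = build_state_network(candidate_pairs(lnc, mrna), expr, "control")
        assert net.n_edges() == 0

    def test_missing_transcripts_skipped(self):
        lnc = table(LNCRNA, [("L", f"m{i}") for i in range(4)])
        mrna = table(MRNA, [("G", f"m{i}") for i in range(4)])
        expr = make_expression({"other": [1, 2, 3, 4, 5]}, ["control"] * 5)
        net = build_state_network(candidate_pairs(lnc, mrna), expr, "control")
        assert net.n_edges() == 0

    def test_too_few_state_samples_rejected(self):
        expr = make_expression({"L": [1, 2, 3], "G": [1, 2, 3]}, ["control"] * 3)
        with pytest.raises(ValueError):
            build_state_network([], expr, "control")

    def test_matches_exhaustive_filter(self, small_config):
        """Edge set equals the brute-force filter over all candidates."""
        lnc, mrna, truth = generate_interactions(small_config)
        expr = generate_expression(small_config, truth)
        cands = candidate_pairs(lnc, mrna)
        for state in expr.states:
            cols = expr.samples_in(state)
            expected = set()
            for c in cands:
                rho = stats.spearmanr(expr.values.loc[c.lncrna, cols],
                                      expr.values.loc[c.mrna, cols]).statistic
                if rho >= 0.9 - 1e-9:
                    expected.add((c.lncrna, c.mrna))
            net = build_state_network(cands, expr, state, rho_min=0.9)
            assert net.edge_ids == expected
            assert all(e.rho >= 0.9 - 1e-9 for e in net.edges.values())

    def test_rank_invariance_under_exp_transform(self, small_config):
        lnc, mrna, truth = generate_interactions(small_config)
        expr = generate_expression(small_config, truth)
        cands = candidate_pairs(lnc, mrna)
        transformed = ExpressionMatrix(
            values=np.exp(expr.values), state_of=expr.state_of,
            transcript_kind=expr.transcript_kind, de_flag=expr.de_flag,
        )
        for state in expr.states:
            a = build_state_network(cands, expr, state)
            b = build_state_network(cands, transformed, state)
            assert a.edge_ids == b.edge_ids


class TestDegreeAndAxes:
    def test_empty_network_empty_table(self):
        net = make_network("control", [])
        assert degree_table(net, LNCRNA) == []

    def test_star_network_degree(self):
        net = make_network("control", [("L1", f"G{i}", 0.95) for i in range(5)])
        assert degree_table(net, LNCRNA) == [("L1", 5)]
        assert degree_table(net, MRNA) == [(f"G{i}", 1) for i in range(5)]

    def test_degree_sums_equal_edge_count(self, small_config):
        lnc, mrna, truth = generate_interactions(small_config)
        expr = generate_expression(small_config, truth)
        net = build_state_network(candidate_pairs(lnc, mrna), expr, "control")
        for side in (LNCRNA, MRNA):
            assert sum(d for _, d in degree_table(net, side)) == net.n_edges()

    def test_ties_broken_lexicographically(self):
        net = make_network("control", [("Lb", "G1", 0.95), ("La", "G2", 0.95)])
        assert degree_table(net, LNCRNA) == [("La", 1), ("Lb", 1)]

    def test_axis_triples_enumerate_shared_mirnas(self, small_config):
        """Triple count per lncRNA = sum of shared_count over its edges."""
        lnc, mrna, truth = generate_interactions(small_config)
        expr = generate_expression(small_config, truth)
        net = build_state_network(candidate_pairs(lnc, mrna), expr, "control")
        for l in net.lncrnas:
            triples = extract_axes(net, lnc, mrna, l)
            expected = sum(e.shared_count for (a, _), e in net.edges.items() if a == l)
            assert len(triples) == expected
            for (a, mir, g) in triples:
                assert a == l
                assert mir in lnc.targets_of(a) & mrna.targets_of(g)

    def test_absent_lncrna_empty_axes(self, toy_tables):
        lnc, mrna = toy_tables
        net = make_network("control", [])
        assert extract_axes(net, lnc, mrna, "nope") == []
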