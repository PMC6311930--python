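import numpy as np
import pandas as pd
import pytest

from adrpair.io import TripartiteNetwork, canonical_pair
from adrpair.scoring import (
    CapacityError,
    inter_d,
    inter_g,
    inter_gd,
    rank_pairs,
    score_all_pairs,
    score_pair,
    select_negatives,
)

from conftest import brute_force_score, random_network


class TestComponents:
    def test_inter_g_hand_values(self):
        assert inter_g({"g1", "g2"}, {"g1", "g2"}) == 1.0
        assert inter_g({"g1", "g2"}, {"g2", "g3"}) == pytest.approx(1 / 3)
        assert inter_g(set(), set()) == 0.0

    def test_inter_d_hand_values(self):
        assert inter_d({"d1"}, {"d1"}, 10) == pytest.approx(0.1)
        assert inter_d({"d1"}, {"d2"}, 10) == 0.0
        vd = {f"d{i}" for i in range(4)}
        assert inter_d(vd, vd, 4) == 1.0
        with pytest.raises(ValueError):
            inter_d({"d1"}, {"d1"}, 0)

    def test_inter_gd_hand_values(self):
        assert inter_gd({"g1", "g2", "g3"}, {"g1", "g2"}, [{"g1", "g5"}]) == 0.5
        assert inter_gd({"g1"}, {"g1"}, []) == 0.0
        assert inter_gd(set(), {"g1"}, [{"g1"}]) == 0.0
        # every shared gene covered by some shared disease
        assert inter_gd({"g1", "g2"}, {"g1", "g2"}, [{"g1"}, {"g2", "g9"}]) == 1.0


def small_network():
    return TripartiteNetwork(
        drugs={"R1", "R2", "R3"},
        diseases={"d1", "d2"},
        genes={"g1", "g2", "g3"},
        drug_genes={"R1": frozenset({"g1", "g2"}), "R2": frozenset({"g2", "g3"})},
        drug_diseases={"R1": frozenset({"d1"}), "R2": frozenset({"d1", "d2"})},
        disease_genes={"d1": frozenset({"g2"})},
    )


def test_score_pair_components_and_sum():
    net = small_network()
    s = score_pair("R2", "R1", net)  # order-insensitive
    assert (s.drug_a, s.drug_b) == ("R1", "R2")
    assert s.inter_g == pytest.approx(1 / 3)
    assert s.inter_d == pytest.approx((1 / 2) * (1 / 2))
    assert s.inter_gd == pytest.approx(1.0)  # shared gene g2 is d1's gene
    assert s.inter_score == s.inter_g + s.inter_d + s.inter_gd


def test_fully_disjoint_pair_scores_zero():
    net = small_network()
    assert score_pair("R1", "R3", net).inter_score == 0.0


def test_maximal_pair_scores_three():
    vd = frozenset({"d1", "d2"})
    g = frozenset({"g1", "g2"})
    net = TripartiteNetwork(
        drugs={"R1", "R2"}, diseases=set(vd), genes=set(g),
        drug_genes={"R1": g, "R2": g},
        drug_diseases={"R1": vd, "R2": vd},
        disease_genes={"d1": g, "d2": g},
    )
    assert score_pair("R1", "R2", net).inter_score == pytest.approx(3.0)


def test_unknown_drug_raises():
    with pytest.raises(KeyError):
        score_pair("R1", "nope", small_network())


def test_vectorised_scorer_matches_brute_force():
    """All four score fields agree with an independent nested-loop oracle
    on many small random tripartite networks."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        net = random_network(rng)
        table = score_all_pairs(net)
        for row in table.itertuples(index=False):
            ref = brute_force_score(row.drug_a, row.drug_b, net)
            for f in ("inter_g", "inter_d", "inter_gd", "inter_score"):
                assert getattr(row, f) == pytest.approx(ref[f], abs=1e-12)


def test_score_symmetry_via_brute_force():
    rng = np.random.default_rng(7)
    net = random_network(rng)
    for a, b in [(x, y) for x in net.drugs for y in net.drugs if x < y][:10]:
        assert brute_force_score(a, b, net) == brute_force_score(b, a, net)
        s = score_pair(a, b, net)
        assert 0 <= s.inter_g <= 1 and 0 <= s.inter_d <= 1 and 0 <= s.inter_gd <= 1
        assert 0 <= s.inter_score <= 3


class TestRanking:
    def test_pair_count_and_sorted(self):
        ranked = rank_pairs(small_network())
        assert len(ranked) == 3
        assert ranked["inter_score"].is_monotonic_increasing

    def test_ranking_deterministic_under_input_shuffle(self):
        rng = np.random.default_rng(3)
        net = random_network(rng)
        r1 = rank_pairs(net)
        shuffled = TripartiteNetwork(
            drugs=set(list(net.drugs)[::-1]),
            diseases=net.diseases,
            genes=net.genes,
            drug_genes=dict(reversed(list(net.drug_genes.items()))),
            drug_diseases=net.drug_diseases,
            disease_genes=net.disease_genes,
        )
        pd.testing.assert_frame_equal(r1, rank_pairs(shuffled))

    def test_tie_break_lexicographic(self):
        ranked = rank_pairs(small_network())
        zeros = ranked[ranked.inter_score == 0]
        keys = list(zip(zeros.drug_a, zeros.drug_b))
        assert keys == sorted(keys)


class TestSelectNegatives:
    @pytest.fixture()
    def ranked(self):
        pairs = [canonical_pair(f"R{i}", f"R{j}") for i in range(8) for j in range(i + 1, 8)]
        pairs.sort()
        return pd.DataFrame(
            {
                "drug_a": [p[0] for p in pairs],
                "drug_b": [p[1] for p in pairs],
                "inter_score": np.linspace(0, 1, len(pairs)),
            }
        )

    def test_prefix_skips_positives(self, ranked):
        positives = set(zip(ranked.drug_a[:3], ranked.drug_b[:3]))
        negs = select_negatives(ranked, positives, nsr=1.0)
        assert len(negs) == 3
        expected = list(zip(ranked.drug_a[3:6], ranked.drug_b[3:6]))
        assert negs == expected
        assert not set(negs) & positives

    def test_nsr_scaling_and_rounding(self, ranked):
        positives = set(zip(ranked.drug_a[:10], ranked.drug_b[:10]))
        assert len(select_negatives(ranked, positives, nsr=0.5)) == 5
        assert len(select_negatives(ranked, positives, nsr=1.0)) == 10
        # round-half-to-even: 0.5 * 3 positives = 1.5 -> 2
        small = set(zip(ranked.drug_a[:3], ranked.drug_b[:3]))
        assert len(select_negatives(ranked, small, nsr=0.5)) == 2

    def test_capacity_error_reports_shortfall(self, ranked):
        positives = set(zip(ranked.drug_a, ranked.drug_b))
        with pytest.raises(CapacityError):
            select_negatives(ranked, positives, nsr=1.0)

    def test_nsr_must_be_positive(self, ranked):
        with pytest.raises(ValueError):
            select_negatives(ranked, set(), nsr=0)
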