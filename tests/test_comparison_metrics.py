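import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netbackbone.backbone_extraction import Backbone, extract_backbone
from netbackbone.comparison_metrics import (
    common_node_proportion,
    compare_backbones,
    compare_pair,
    effectiveness,
    kendall_tau,
    pearson_correlation,
    rank_biased_overlap,
    top_t_overlap,
)
from netbackbone.graph_io import rank_nodes
from netbackbone.synthetic_data import PlantedOverlapSpec, generate

from conftest import make_weighted


def ranking(names_values):
    """Build a ranked-list-shaped sequence of (node, value) pairs."""
    return list(names_values)


class TestCommonNodeProportion:
    def test_identical(self):
        assert common_node_proportion({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert common_node_proportion({"a"}, {"b"}) == 0.0

    def test_half(self):
        assert common_node_proportion({"a", "b", "c", "d"}, {"a", "b", "x", "y"}) == 0.5

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            common_node_proportion(set(), set())

    def test_unequal_sizes_warn_and_use_min(self):
        with pytest.warns(UserWarning, match="differ"):
            value = common_node_proportion({"a", "b", "c"}, {"a", "b"})
        assert value == 1.0


class TestTopTOverlap:
    def test_backbone_with_all_top_nodes(self, karate):
        top = [e.node for e in rank_nodes(karate)[:5]]
        assert top_t_overlap(karate, set(top), 0.1) == 1.0

    def test_backbone_missing_all_top_nodes(self, karate):
        bottom = [e.node for e in rank_nodes(karate)[-5:]]
        assert top_t_overlap(karate, set(bottom), 0.1) == 0.0

    def test_small_backbone_warns(self, karate):
        node = rank_nodes(karate)[0].node
        with pytest.warns(UserWarning, match="smaller"):
            value = top_t_overlap(karate, {node}, 0.1)
        assert value == pytest.approx(1 / 3)


class TestRankBiasedOverlap:
    def test_identical_lists_normalized_to_one(self):
        x = ranking([("a", 3), ("b", 2), ("c", 1)])
        assert rank_biased_overlap(x, x, 0.5) == pytest.approx(1.0)

    def test_disjoint_lists_zero(self):
        x = ranking([("a", 3), ("b", 2)])
        y = ranking([("c", 3), ("d", 2)])
        assert rank_biased_overlap(x, y, 0.7) == 0.0

    def test_hand_computed_example(self):
        x = ranking([("a", 3), ("b", 2), ("c", 1)])
        y = ranking([("b", 3), ("a", 2), ("c", 1)])
        raw = rank_biased_overlap(x, y, 0.5, normalized=False)
        assert raw == pytest.approx(0.375)
        assert rank_biased_overlap(x, y, 0.5) == pytest.approx(0.375 / 0.875)

    def test_invalid_p(self):
        x = ranking([("a", 1)])
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                rank_biased_overlap(x, x, p)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_biased_overlap([], [("a", 1)], 0.5)

    def test_symmetric(self, rng):
        names = [f"n{i}" for i in range(12)]
        for _ in range(20):
            x = [(v, 1.0) for v in rng.permutation(names)]
            y = [(v, 1.0) for v in rng.permutation(names)[:8]]
            for p in (0.5, 0.9):
                assert rank_biased_overlap(x, y, p) == pytest.approx(
                    rank_biased_overlap(y, x, p)
                )

    def test_appending_agreeing_element_never_decreases(self, rng):
        x = [(f"n{i}", 1.0) for i in range(6)]
        y = [(v, 1.0) for v in rng.permutation([n for n, _ in x])]
        before = rank_biased_overlap(x, y, 0.8)
        x2 = x + [("zz", 0.5)]
        y2 = y + [("zz", 0.5)]
        assert rank_biased_overlap(x2, y2, 0.8) >= before - 1e-12

    def test_matches_direct_summation_oracle(self, rng):
        """Direct evaluation: per-depth prefix intersections, geometric weights."""
        names = [f"n{i}" for i in range(15)]
        for trial in range(30):
            kx = int(rng.integers(1, 15))
            ky = int(rng.integers(1, 15))
            x = [(v, 1.0) for v in rng.permutation(names)[:kx]]
            y = [(v, 1.0) for v in rng.permutation(names)[:ky]]
            d_max = min(kx, ky)
            for p in (0.5, 0.7, 0.9, 0.98):
                direct = sum(
                    (1 - p)
                    * p ** (d - 1)
                    * len(
                        {n for n, _ in x[:d]} & {n for n, _ in y[:d]}
                    )
                    / d
                    for d in range(1, d_max + 1)
                )
                assert rank_biased_overlap(x, y, p, normalized=False) == pytest.approx(
                    direct, abs=1e-12
                )
                assert rank_biased_overlap(x, y, p) == pytest.approx(
                    direct / (1 - p**d_max), abs=1e-12
                )

    @given(
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=0, max_value=10**6),
        st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_range_bounds_fuzz(self, n, seed, p):
        rng = np.random.default_rng(seed)
        pool = [f"n{i}" for i in range(30)]
        x = [(v, 1.0) for v in rng.permutation(pool)[:n]]
        y = [(v, 1.0) for v in rng.permutation(pool)[: max(1, n // 2)]]
        value = rank_biased_overlap(x, y, p)
        assert 0.0 <= value <= 1.0 + 1e-12


class TestPearson:
    def test_perfect_linear(self):
        x = [1, 2, 3, 4]
        y = [2 * v + 1 for v in x]
        assert pearson_correlation(x, y) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 5.0]
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        x = (1, 2, 3, 5)
        y = (2, 1, 4, 5)
        xm, ym = sum(x) / 4, sum(y) / 4
        num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - xm) ** 2 for a in x) * sum((b - ym) ** 2 for b in y)
        )
        assert pearson_correlation(x, y) == pytest.approx(num / den)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson_correlation([1], [2])

    def test_matches_scipy(self, rng):
        from scipy import stats

        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert pearson_correlation(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic
            )

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_range_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert -1.0 - 1e-12 <= pearson_correlation(x, y) <= 1.0 + 1e-12


class TestKendallTau:
    def test_identical_rankings(self):
        x = ranking([("a", 9), ("b", 5), ("c", 2), ("d", 1)])
        assert kendall_tau(x, x) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        x = ranking([("a", 4), ("b", 3), ("c", 2), ("d", 1)])
        y = ranking([("a", 1), ("b", 2), ("c", 3), ("d", 4)])
        assert kendall_tau(x, y) == pytest.approx(-1.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            kendall_tau([("a", 1)], [("a", 1)])

    def test_matches_all_pairs_enumeration(self, rng):
        for trial in range(20):
            n = 8
            x = [(f"n{i}", float(rng.integers(1, 6))) for i in range(n)]
            y = [(f"n{i}", float(rng.integers(1, 6))) for i in range(n)]

            def dense(vals):
                order = sorted(set(vals), reverse=True)
                return [order.index(v) + 1 for v in vals]

            rx = dense([v for _, v in x])
            ry = dense([v for _, v in y])
            n_c = n_d = 0
            for i, j in itertools.combinations(range(n), 2):
                dx = rx[i] - rx[j]
                dy = ry[i] - ry[j]
                if dx * dy > 0:
                    n_c += 1
                elif dx * dy < 0:
                    n_d += 1
            expected = (n_c - n_d) / (n * (n - 1) / 2)
            assert kendall_tau(x, y) == pytest.approx(expected)

    def test_monotone_transform_gives_one(self, rng):
        values = sorted(rng.choice(1000, size=10, replace=False), reverse=True)
        x = [(f"n{i}", float(v)) for i, v in enumerate(values)]
        y = [(f"n{i}", float(2 * v + 3)) for i, v in enumerate(values)]
        assert kendall_tau(x, y) == pytest.approx(1.0)
        assert pearson_correlation(
            [v for _, v in x], [math.exp(v / 500) for _, v in x]
        ) > 0.9


class TestEffectiveness:
    def test_star_closed_form(self):
        g = make_weighted([("c", f"l{i}", 1) for i in range(4)])
        bb = Backbone(subgraph=g, method="ego")
        beta, k, w = effectiveness(bb)
        assert beta == pytest.approx(0.2)
        assert w == pytest.approx(1.0)
        assert k == pytest.approx((4 + 1 + 1 + 1 + 1) / 5)

    def test_clique_zero_betweenness(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 2.0, "weight")
        beta, k, w = effectiveness(Backbone(subgraph=g, method="ego"))
        assert beta == 0.0
        assert k == pytest.approx(8.0)
        assert w == pytest.approx(2.0)

    def test_tiny_graph_beta_convention(self):
        g = make_weighted([("a", "b", 3)])
        beta, k, w = effectiveness(Backbone(subgraph=g, method="ego"))
        assert beta == 0.0
        assert w == 3.0

    def test_empty_backbone_rejected(self):
        with pytest.raises(ValueError):
            effectiveness(Backbone(subgraph=nx.Graph(), method="ego"))

    def test_matches_brute_force_oracle(self):
        g, _ = generate(PlantedOverlapSpec(n_communities=2, community_size=8, seed=9))
        sub = g.subgraph(sorted(g.nodes)[:15]).copy()
        bb = Backbone(subgraph=sub, method="ego")
        beta, k, w = effectiveness(bb)
        # betweenness via explicit all-shortest-paths enumeration
        nodes = sorted(sub.nodes)
        n = len(nodes)
        score = dict.fromkeys(nodes, 0.0)
        for s, t in itertools.combinations(nodes, 2):
            if not nx.has_path(sub, s, t):
                continue
            paths = list(nx.all_shortest_paths(sub, s, t))
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                if through:
                    score[v] += through / len(paths)
        norm = (n - 1) * (n - 2) / 2
        assert beta == pytest.approx(np.mean([score[v] / norm for v in nodes]))
        assert k == pytest.approx(
            np.mean([sub.degree(v, weight="weight") for v in nodes])
        )
        assert w == pytest.approx(
            np.mean([d["weight"] for *_, d in sub.edges(data=True)])
        )


class TestCompareBackbones:
    def test_identical_backbones_all_ones(self, karate):
        # tie-free weighted degrees, otherwise tau_a < 1 by the tie clause
        sub = karate.subgraph(["0", "1", "2", "3", "4", "5", "6", "8", "9"]).copy()
        b1 = Backbone(subgraph=sub.copy(), method="ego")
        b2 = Backbone(subgraph=sub.copy(), method="hubs")
        report = compare_backbones(karate, [[b1, b2]])
        assert report.means[("A_n", "ego-hubs")] == pytest.approx(1.0)
        assert report.means[("kendall", "ego-hubs")] == pytest.approx(1.0)
        assert report.means[("pearson", "ego-hubs")] == pytest.approx(1.0)
        for p in (0.5, 0.7, 0.8, 0.9, 0.98):
            assert report.means[(f"rbo_p{p}", "ego-hubs")] == pytest.approx(1.0)
        assert all(s == 0.0 for s in report.stds.values())

    def test_synthetic_df_less_similar_than_hubs(self):
        """Averaged over 20 generator draws the proposed backbones agree with
        each other more than with the calibrated disparity filter."""
        diffs = []
        for seed in range(20):
            spec = PlantedOverlapSpec(
                n_communities=2, community_size=12, p_in=0.8, p_out=0.02, seed=seed
            )
            g, cover = generate(spec)
            oe = extract_backbone(g, cover=cover, method="ego", s=0.5)
            oh = extract_backbone(g, cover=cover, method="hubs", s=0.5)
            df = extract_backbone(g, method="disparity", s=0.5)
            pair_oh = compare_pair(g, oe, oh)["A_n"]
            pair_df = compare_pair(g, oe, df)["A_n"]
            diffs.append(pair_oh - pair_df)
        assert float(np.mean(diffs)) > 0

    def test_report_frame_shape(self, karate):
        sub = karate.subgraph([str(i) for i in range(8)]).copy()
        b1 = Backbone(subgraph=sub.copy(), method="ego")
        b2 = Backbone(subgraph=sub.copy(), method="hubs")
        report = compare_backbones(karate, [[b1, b2], [b1, b2]])
        frame = report.to_frame()
        assert set(frame.columns) == {"measure", "subject", "mean", "std"}
        assert report.n_runs == 2

    def test_needs_two_backbones(self, karate):
        sub = karate.subgraph(["0", "1"]).copy()
        with pytest.raises(ValueError):
            compare_backbones(karate, [[Backbone(subgraph=sub, method="ego")]])
        with pytest.raises(ValueError):
            compare_backbones(karate, [])
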