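"""Degree-preserving rewiring, Monte Carlo p-values, density enrichment."""

import networkx as nx
import numpy as np
import pytest

from hsnet import netio, nullmodels
from hsnet.nullmodels import (
    degree_preserving_rewire,
    density_enrichment,
    edge_count_random_graph,
    empirical_p_value,
    modularity_null_pvalue,
)


class TestRewire:
    @pytest.mark.parametrize("seed", range(4))
    def test_preserves_degree_sequence_and_simplicity(self, seed):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(25, 0.2, seed=seed), lambda i: f"v{i}"
        )
        rewired = degree_preserving_rewire(
            g, 10 * g.number_of_edges(), seed=seed
        )
        assert dict(rewired.degree()) == dict(g.degree())
        assert set(rewired.nodes) == set(g.nodes)
        assert rewired.number_of_edges() == g.number_of_edges()
        assert not any(u == v for u, v in rewired.edges())

    def test_four_cycle_stays_a_four_cycle(self):
        # The only simple graphs reachable from C4 by double swaps are
        # 4-cycles on the same nodes (enumerated by hand).
        g = nx.relabel_nodes(nx.cycle_graph(4), str)
        rewired = degree_preserving_rewire(g, 8, seed=3)
        assert sorted(d for _, d in rewired.degree()) == [2, 2, 2, 2]
        assert nx.is_connected(rewired)

    def test_same_seed_is_deterministic(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(15, 0.3, seed=2), str)
        a = degree_preserving_rewire(g, 50, seed=9)
        b = degree_preserving_rewire(g, 50, seed=9)
        assert {frozenset(e) for e in a.edges()} == {
            frozenset(e) for e in b.edges()
        }

    def test_star_returned_unchanged_with_warning(self, caplog):
        star = nx.relabel_nodes(nx.star_graph(5), str)
        with caplog.at_level("WARNING"):
            rewired = degree_preserving_rewire(star, 10, seed=0)
        assert {frozenset(e) for e in rewired.edges()} == {
            frozenset(e) for e in star.edges()
        }
        assert "unchanged" in caplog.text

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError):
            degree_preserving_rewire(nx.Graph([("a", "b")]), 5, seed=0)


def test_edge_count_null_preserves_counts_only():
    g = nx.relabel_nodes(nx.barbell_graph(5, 0), str)
    null = edge_count_random_graph(g, seed=4)
    assert set(null.nodes) == set(g.nodes)
    assert null.number_of_edges() == g.number_of_edges()


class TestEmpiricalP:
    def test_pseudocount_bounds(self):
        assert empirical_p_value(10.0, [0.0] * 99) == pytest.approx(1 / 100)
        assert empirical_p_value(-1.0, [0.0] * 99) == pytest.approx(1.0)

    def test_ties_count_as_exceedances(self):
        assert empirical_p_value(1.0, [1.0, 0.5, 2.0]) == pytest.approx(3 / 4)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            empirical_p_value(1.0, [])


class TestModularityNull:
    def test_planted_clique_pair_is_significant(self, clique_pair_bridge):
        null = modularity_null_pvalue(
            clique_pair_bridge, n_realizations=99, seed=1, optimizer="greedy"
        )
        assert null.p_value == pytest.approx(1 / 100)
        assert null.observed > max(null.samples)

    def test_p_respects_pseudocount_bounds(self, clique_pair_bridge):
        null = modularity_null_pvalue(
            clique_pair_bridge, n_realizations=19, seed=0, optimizer="greedy"
        )
        assert 1 / 20 <= null.p_value <= 1.0
        assert null.n_realizations == 19
        assert len(null.samples) == 19

    def test_disconnected_input_rejected(self, two_triangles):
        with pytest.raises(ValueError, match="largest component"):
            modularity_null_pvalue(two_triangles, n_realizations=9, seed=0)

    def test_zero_realizations_rejected(self, clique_pair_bridge):
        with pytest.raises(ValueError):
            modularity_null_pvalue(clique_pair_bridge, n_realizations=0)

    def test_null_statistic_distribution_is_calibrated(self):
        # A graph drawn from the null, tested against its own null, should
        # give p-values spread over (0, 1] rather than piling up at either
        # end; checked coarsely with a KS statistic against uniform.
        from scipy import stats

        base = netio.largest_component(
            nx.relabel_nodes(nx.gnp_random_graph(13, 0.35, seed=3), str)
        )
        p_values = []
        for repeat in range(20):
            realization = netio.largest_component(
                degree_preserving_rewire(
                    base, 10 * base.number_of_edges(), seed=100 + repeat
                )
            )
            null = modularity_null_pvalue(
                realization, n_realizations=49, seed=repeat, optimizer="greedy"
            )
            p_values.append(null.p_value)
        assert 0.2 <= float(np.median(p_values)) <= 0.8
        ks = stats.kstest(p_values, "uniform")
        assert ks.statistic < 0.4  # coarse: discrete grid, 20 repeats

    def test_planting_edges_never_raises_the_p_value(self):
        # Adding within-module edges strengthens planted structure: along a
        # nested family (random graph -> a few within-half chords -> both
        # halves completed) the p-value must not increase.
        base = netio.largest_component(
            nx.relabel_nodes(
                nx.gnp_random_graph(12, 0.3, seed=4), lambda i: f"v{i}"
            )
        )
        nodes = sorted(base.nodes)
        groups = [nodes[: len(nodes) // 2], nodes[len(nodes) // 2 :]]
        g1 = base.copy()
        for group in groups:
            g1.add_edges_from(
                [(group[0], group[2]), (group[1], group[3]), (group[0], group[4])]
            )
        g2 = g1.copy()
        for group in groups:
            g2.add_edges_from(
                (a, b) for i, a in enumerate(group) for b in group[i + 1 :]
            )
        p_values = [
            modularity_null_pvalue(
                g, n_realizations=99, seed=11, optimizer="greedy"
            ).p_value
            for g in (base, g1, g2)
        ]
        assert p_values[0] >= p_values[1] >= p_values[2]
        assert p_values[2] == pytest.approx(1 / 100)


class TestDensityEnrichment:
    def test_whole_network_gene_set_is_null(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(30, 0.2, seed=1), str)
        result = density_enrichment(g, set(g.nodes), n_samples=49, seed=0)
        assert result.ratio == pytest.approx(1.0)
        assert result.null.p_value == pytest.approx(1.0)

    def test_planted_clique_hits_the_p_floor(self):
        bg = nx.relabel_nodes(
            nx.gnp_random_graph(200, 0.02, seed=7), lambda i: f"g{i}"
        )
        clique = [f"g{i}" for i in range(6)]
        bg.add_edges_from(
            (a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]
        )
        result = density_enrichment(bg, clique, n_samples=999, seed=2)
        assert result.null.p_value == pytest.approx(1 / 1000)
        assert result.observed_density == pytest.approx(1.0)

    def test_edgeless_gene_set_has_zero_ratio(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        g.add_nodes_from(["x", "y"])
        result = density_enrichment(g, {"x", "y"}, n_samples=19, seed=0)
        assert result.observed_density == 0.0
        assert result.ratio == 0.0

    def test_unmapped_ids_dropped_softly(self, caplog):
        g = nx.Graph([("a", "b"), ("b", "c")])
        with caplog.at_level("WARNING"):
            result = density_enrichment(
                g, {"a", "b", "missing"}, n_samples=19, seed=0
            )
        assert "missing" in caplog.text
        assert result.observed_density == pytest.approx(1.0)

    def test_fewer_than_two_mapped_genes_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            density_enrichment(g, {"a", "zz"}, n_samples=9, seed=0)


def test_null_samples_dump(tmp_path, clique_pair_bridge):
    null = modularity_null_pvalue(
        clique_pair_bridge, n_realizations=9, seed=0, optimizer="greedy"
    )
    nullmodels.write_null_samples(null, tmp_path / "null.tsv")
    lines = (tmp_path / "null.tsv").read_text().splitlines()
    assert lines[0] == "max_modularity"
    assert len(lines) == 10
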