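"""Planted-partition interactome generator and tissue-label simulation."""

import networkx as nx
import numpy as np
import pytest

from hsnet import netio
from hsnet.community import greedy_max_modularity
from hsnet.concordance import adjusted_rand_index, purity
from hsnet.nullmodels import modularity_null_pvalue
from hsnet.synthetic import (
    DEFAULT_LABEL_SPACE,
    PlantedSpec,
    generate_planted_network,
    generate_tissue_labels,
    module_sizes,
    save_bundle,
)


def small_spec(**overrides):
    defaults = dict(
        n_background=150,
        background_mean_degree=4.0,
        n_regulators=30,
        n_modules=3,
        p_in=0.6,
        p_out=0.02,
        connect_fraction=1.0,
    )
    defaults.update(overrides)
    return PlantedSpec(**defaults)


class TestPlantedSpec:
    def test_infeasible_probabilities_rejected(self):
        with pytest.raises(ValueError, match="p_out < p_in"):
            PlantedSpec(p_in=0.1, p_out=0.2)
        with pytest.raises(ValueError, match="p_out < p_in"):
            PlantedSpec(p_in=0.3, p_out=0.3)

    def test_module_sizes_near_equal_with_remainder_first(self):
        assert module_sizes(52, 3) == [18, 17, 17]
        assert module_sizes(9, 3) == [3, 3, 3]


class TestGenerator:
    def test_same_seed_gives_identical_networks(self):
        spec = small_spec()
        a = generate_planted_network(spec, seed=5)
        b = generate_planted_network(spec, seed=5)
        assert {frozenset(e) for e in a.network.edges()} == {
            frozenset(e) for e in b.network.edges()
        }
        assert a.labels == b.labels

    def test_network_is_simple(self):
        bundle = generate_planted_network(small_spec(), seed=1)
        g = bundle.network
        assert not any(u == v for u, v in g.edges())
        assert isinstance(g, nx.Graph)  # multi-edges impossible by type

    def test_partition_covers_exactly_the_regulators(self):
        bundle = generate_planted_network(small_spec(), seed=2)
        assert (
            set(bundle.planted_partition.assignment) == bundle.regulator_ids
        )

    def test_limit_case_disjoint_cliques(self):
        spec = small_spec(
            n_background=0, background_mean_degree=0.0, p_in=1.0, p_out=0.0
        )
        bundle = generate_planted_network(spec, seed=0)
        sub = netio.induced_subgraph(bundle.network, bundle.regulator_ids)
        summary = netio.connected_components(sub)
        assert summary.component_sizes == (10, 10, 10)
        for module_members in bundle.planted_partition.modules():
            clique = netio.induced_subgraph(sub, module_members)
            assert netio.edge_density(clique) == pytest.approx(1.0)

    def test_connect_fraction_controls_giant_component(self):
        spec = PlantedSpec(
            n_background=100,
            n_regulators=52,
            connect_fraction=39 / 52,
            p_in=0.6,
            p_out=0.02,
        )
        sizes = []
        for seed in range(5):
            bundle = generate_planted_network(spec, seed=seed)
            sub = netio.induced_subgraph(bundle.network, bundle.regulator_ids)
            sizes.append(netio.connected_components(sub).largest_size)
        # wired set is 39 genes; the giant component is that set (or nearly
        # so when an inter-module link is missing by chance)
        assert np.median(sizes) >= 30
        assert max(sizes) <= 39

    def test_heavy_tailed_background_degrees(self):
        bundle = generate_planted_network(
            small_spec(n_background=1000), seed=3
        )
        degrees = [
            d for n, d in bundle.network.degree() if n.startswith("bg")
        ]
        # preferential attachment: a hub far above the mean degree
        assert max(degrees) > 5 * np.mean(degrees)

    def test_recovery_improves_with_contrast(self):
        # ARI of detected vs planted modules is non-decreasing (on average)
        # in the p_in/p_out contrast.
        grid = [(0.15, 0.10), (0.30, 0.05), (0.60, 0.02)]
        means = []
        for p_in, p_out in grid:
            aris = []
            for seed in range(10):
                bundle = generate_planted_network(
                    small_spec(p_in=p_in, p_out=p_out), seed=seed
                )
                sub = netio.induced_subgraph(
                    bundle.network, bundle.regulator_ids
                )
                giant = netio.largest_component(sub)
                detected = greedy_max_modularity(giant)
                planted = {
                    n: bundle.planted_partition.assignment[n]
                    for n in giant.nodes
                }
                aris.append(
                    adjusted_rand_index(
                        planted, dict(detected.partition.assignment)
                    )
                )
            means.append(float(np.mean(aris)))
        assert means[0] <= means[1] + 0.05
        assert means[1] <= means[2] + 0.05
        assert means[2] > 0.9

    def test_null_p_tracks_planted_contrast(self):
        # Strong planted structure pins the modularity null p-value to its
        # pseudocount floor; weak structure drifts toward uniformity.
        def median_p(p_in, p_out):
            values = []
            for seed in range(3):
                bundle = generate_planted_network(
                    small_spec(p_in=p_in, p_out=p_out, n_background=0),
                    seed=seed,
                )
                sub = netio.induced_subgraph(
                    bundle.network, bundle.regulator_ids
                )
                giant = netio.largest_component(sub)
                values.append(
                    modularity_null_pvalue(
                        giant,
                        n_realizations=49,
                        seed=seed,
                        optimizer="greedy",
                    ).p_value
                )
            return float(np.median(values))

        weak = median_p(0.22, 0.18)
        strong = median_p(0.60, 0.02)
        assert strong == pytest.approx(1 / 50)
        assert weak > strong


class TestTissueLabels:
    def test_zero_flip_rate_gives_pure_modules(self):
        assignment = {f"n{k}": k % 3 for k in range(30)}
        labels = generate_tissue_labels(assignment, flip_rate=0.0, seed=0)
        assert purity(assignment, labels) == pytest.approx(1.0)

    def test_uniformizing_flip_rate_destroys_agreement(self):
        # With two labels, flipping to "the other" at rate 1/2 makes the
        # label marginal uniform and independent of the modules, so ARI
        # averages to zero and purity to its 1/2 baseline.
        assignment = {f"n{k}": k % 2 for k in range(40)}
        aris = []
        purities = []
        for seed in range(10):
            labels = generate_tissue_labels(
                assignment, flip_rate=0.5, label_space=("x", "y"), seed=seed
            )
            aris.append(adjusted_rand_index(assignment, labels))
            purities.append(purity(assignment, labels))
        assert abs(float(np.mean(aris))) < 0.2
        assert 0.5 <= float(np.mean(purities)) < 0.75

    def test_full_flip_with_two_labels_is_the_complement_bijection(self):
        # At flip rate 1 with a two-label space every node takes the other
        # label deterministically: as a grouping this is identical to the
        # modules (ARI stays 1) even though no node keeps its canonical
        # label.
        assignment = {f"n{k}": k % 2 for k in range(10)}
        labels = generate_tissue_labels(
            assignment, flip_rate=1.0, label_space=("x", "y"), seed=0
        )
        assert adjusted_rand_index(assignment, labels) == pytest.approx(1.0)
        assert all(
            labels[node] == ("y" if module == 0 else "x")
            for node, module in assignment.items()
        )

    def test_flip_count_matches_binomial_expectation(self):
        assignment = {f"n{k}": k % 3 for k in range(52)}
        flip_rate = 0.1
        flips = []
        for seed in range(40):
            labels = generate_tissue_labels(assignment, flip_rate, seed=seed)
            canonical = {
                module: DEFAULT_LABEL_SPACE[module]
                for module in range(3)
            }
            flips.append(
                sum(
                    labels[node] != canonical[module]
                    for node, module in assignment.items()
                )
            )
        expected = 52 * flip_rate  # binomial mean 5.2
        assert abs(float(np.mean(flips)) - expected) < 1.5

    def test_label_space_must_cover_modules(self):
        assignment = {"a": 0, "b": 1, "c": 2}
        with pytest.raises(ValueError, match="label space"):
            generate_tissue_labels(assignment, 0.1, label_space=("x", "y"))


def test_save_bundle_writes_all_artifacts(tmp_path):
    bundle = generate_planted_network(small_spec(n_background=50), seed=4)
    save_bundle(bundle, tmp_path)
    for name in (
        "edges.tsv",
        "regulators.txt",
        "planted_partition.tsv",
        "labels.tsv",
        "spec.json",
    ):
        assert (tmp_path / name).exists(), name
    regulators = (tmp_path / "regulators.txt").read_text().split()
    assert len(regulators) == 30
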