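"""Synthetic interactomes with planted module structure.

The real analysis runs against a genome-scale *C. elegans* interactome that
is not redistributable here, so this module generates networks with the same
statistical features the analysis relies on: a sparse, heavy-tailed
background graph (preferential attachment), a set of "regulator" genes
carrying a planted q-module partition (within-module edges much denser than
between-module edges), a tunable fraction of regulators actually wired into
the regulator subnetwork, and tissue labels correlated with the planted
modules at a configurable flip rate.

Defaults echo the observed geometry of the heat-shock regulator network —
52 regulators, 3 modules, 39/52 in the giant component — so the pipeline's
synthetic mode exercises the full analysis at realistic scale. The defaults
are echoes of that geometry, not claims about real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .community import Partition, canonical_labels

#: Tissue categories (spermatheca/intestine/muscle combinations) ordered so
#: that the first three echo the observed module-to-tissue correspondence:
#: spermatheca+intestine (clearance/secretory), muscle-only (cytosolic
#: folding), intestine-only (gene expression & synthesis).
DEFAULT_LABEL_SPACE: tuple[str, ...] = (
    "SI-",
    "--M",
    "-I-",
    "SIM",
    "S--",
    "-IM",
    "S-M",
    "---",
)

# Fixed substream offsets: one independent RNG per generation stage.
_STREAM_BACKGROUND = 0
_STREAM_PLANT = 1
_STREAM_ATTACH = 2
_STREAM_LABELS = 3


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted-module interactome generator.

    ``p_in``/``p_out`` are Bernoulli edge probabilities within and between
    planted modules (``p_out`` also scales the sparse regulator-background
    attachment); ``connect_fraction`` is the target fraction of regulators
    wired into the regulator subnetwork, the rest staying isolated from it.
    """

    n_background: int = 2000
    background_mean_degree: float = 4.0
    n_regulators: int = 52
    n_modules: int = 3
    p_in: float = 0.6
    p_out: float = 0.02
    connect_fraction: float = 39 / 52
    label_flip_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(
                "planted structure requires 0 <= p_out < p_in <= 1, got "
                f"p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.n_modules < 1 or self.n_regulators < self.n_modules:
            raise ValueError("need at least one regulator per module")
        if not 0.0 <= self.connect_fraction <= 1.0:
            raise ValueError("connect_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ValueError("label_flip_rate must lie in [0, 1]")
        if self.n_background < 0 or self.background_mean_degree < 0:
            raise ValueError("background size and degree must be non-negative")


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated interactome plus the ground truth planted into it."""

    network: nx.Graph
    regulator_ids: frozenset[str]
    planted_partition: Partition
    labels: dict[str, str]
    spec: PlantedSpec


def module_sizes(n_items: int, n_modules: int) -> list[int]:
    """Near-equal module sizes; the remainder goes to the earliest modules."""
    base, remainder = divmod(n_items, n_modules)
    return [base + (1 if i < remainder else 0) for i in range(n_modules)]


def _stream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, seed])


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    scale = total / sum(weights) if sum(weights) else 0.0
    raw = [w * scale for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    leftovers = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in leftovers[: total - sum(counts)]:
        counts[i] += 1
    return counts


def generate_planted_network(
    spec: PlantedSpec,
    seed: int | None = None,
    regulator_ids: Sequence[str] | None = None,
    planted_assignment: Mapping[str, int] | None = None,
) -> SyntheticBundle:
    """Generate a background interactome with a planted regulator subnetwork.

    The background is a preferential-attachment graph (heavy-tailed degrees,
    mean degree ≈ ``background_mean_degree``). Regulators are partitioned
    into ``n_modules`` near-equal planted modules (or per an explicit
    ``planted_assignment``); a ``connect_fraction`` share of each module is
    "wired": wired pairs receive Bernoulli(``p_in``) edges within modules and
    Bernoulli(``p_out``) between, while unwired regulators get no
    regulator-regulator edges at all, emulating screen hits absent from the
    interaction data. Every regulator also attaches to
    Poisson(``background_mean_degree * p_out``) random background genes.
    Fully deterministic for a given seed.
    """
    base_seed = spec.seed if seed is None else seed

    if regulator_ids is None:
        regulator_ids = [f"reg{i:03d}" for i in range(1, spec.n_regulators + 1)]
    regulator_ids = list(regulator_ids)
    if len(regulator_ids) != spec.n_regulators:
        raise ValueError(
            f"got {len(regulator_ids)} regulator IDs for "
            f"n_regulators={spec.n_regulators}"
        )
    if len(set(regulator_ids)) != len(regulator_ids):
        raise ValueError("regulator IDs must be unique")

    if planted_assignment is None:
        sizes = module_sizes(spec.n_regulators, spec.n_modules)
        assignment: dict[str, int] = {}
        cursor = 0
        for module, size in enumerate(sizes):
            for gene in regulator_ids[cursor : cursor + size]:
                assignment[gene] = module
            cursor += size
    else:
        assignment = dict(planted_assignment)
        if set(assignment) != set(regulator_ids):
            raise ValueError(
                "planted_assignment must cover exactly the regulator IDs"
            )
        if len(set(assignment.values())) != spec.n_modules:
            raise ValueError(
                "planted_assignment module count disagrees with n_modules"
            )

    network = _background_graph(spec, base_seed)
    background_nodes = sorted(network.nodes)
    network.add_nodes_from(regulator_ids)

    # Wire a connect_fraction share of each module with planted edges.
    plant_rng = _stream(base_seed, _STREAM_PLANT)
    modules: dict[int, list[str]] = {}
    for gene in regulator_ids:
        modules.setdefault(assignment[gene], []).append(gene)
    module_order = sorted(modules)
    target_wired = round(spec.connect_fraction * spec.n_regulators)
    wired_counts = _largest_remainder(
        [len(modules[m]) for m in module_order], target_wired
    )
    wired: list[str] = []
    for module, count in zip(module_order, wired_counts):
        genes = list(modules[module])
        chosen = plant_rng.choice(len(genes), size=count, replace=False)
        wired.extend(genes[i] for i in sorted(chosen))
    wired_set = set(wired)

    for i, u in enumerate(wired):
        for v in wired[i + 1 :]:
            probability = (
                spec.p_in if assignment[u] == assignment[v] else spec.p_out
            )
            if plant_rng.random() < probability:
                network.add_edge(u, v)

    # connect_fraction promises the wired set forms one component; when the
    # Bernoulli draws leave wired clusters mutually disconnected, add the
    # minimal number of random between-component links to honour it. With
    # p_out = 0 between-module edges are ruled out, so modules stay apart.
    if spec.p_out > 0 and len(wired) > 1:
        wired_sub = network.subgraph(wired_set)
        components = sorted(
            (sorted(c) for c in nx.connected_components(wired_sub)),
            key=lambda c: c[0],
        )
        while len(components) > 1:
            first, second = components[0], components[1]
            u = first[int(plant_rng.integers(len(first)))]
            v = second[int(plant_rng.integers(len(second)))]
            network.add_edge(u, v)
            components = [sorted(first + second)] + components[2:]
            components.sort(key=lambda c: c[0])

    # Sparse regulator-background attachment, scaling with p_out.
    attach_rng = _stream(base_seed, _STREAM_ATTACH)
    if background_nodes:
        rate = spec.background_mean_degree * spec.p_out
        for gene in regulator_ids:
            n_partners = min(
                int(attach_rng.poisson(rate)), len(background_nodes)
            )
            if n_partners == 0:
                continue
            partners = attach_rng.choice(
                len(background_nodes), size=n_partners, replace=False
            )
            for j in partners:
                network.add_edge(gene, background_nodes[j])

    partition = Partition(canonical_labels(assignment))
    labels = generate_tissue_labels(
        partition,
        flip_rate=spec.label_flip_rate,
        label_space=DEFAULT_LABEL_SPACE,
        seed=base_seed,
    )
    return SyntheticBundle(
        network=network,
        regulator_ids=frozenset(regulator_ids),
        planted_partition=partition,
        labels=labels,
        spec=spec,
    )


def _background_graph(spec: PlantedSpec, seed: int) -> nx.Graph:
    """Heavy-tailed sparse background via preferential attachment."""
    if spec.n_background == 0:
        return nx.Graph()
    attach = max(1, round(spec.background_mean_degree / 2.0))
    if spec.n_background <= attach:
        graph = nx.complete_graph(spec.n_background)
    else:
        rng = _stream(seed, _STREAM_BACKGROUND)
        graph = nx.barabasi_albert_graph(spec.n_background, attach, seed=rng)
    return nx.relabel_nodes(
        graph, {i: f"bg{i:05d}" for i in graph.nodes}, copy=True
    )


def generate_tissue_labels(
    partition: Partition | Mapping[str, int],
    flip_rate: float,
    label_space: Sequence[str] = DEFAULT_LABEL_SPACE,
    seed: int = 0,
) -> dict[str, str]:
    """Labels correlated with a partition: each module gets a distinct
    canonical label; each node keeps it with probability ``1 - flip_rate``,
    otherwise drawing uniformly from the remaining labels."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    assignment = (
        dict(partition.assignment)
        if isinstance(partition, Partition)
        else dict(partition)
    )
    module_list = sorted(set(assignment.values()))
    if len(label_space) < len(module_list):
        raise ValueError(
            f"label space of size {len(label_space)} cannot cover "
            f"{len(module_list)} modules"
        )
    if len(set(label_space)) != len(label_space):
        raise ValueError("label space entries must be distinct")
    canonical = {
        module: label_space[i] for i, module in enumerate(module_list)
    }
    rng = _stream(seed, _STREAM_LABELS)
    labels: dict[str, str] = {}
    for node in sorted(assignment):
        label = canonical[assignment[node]]
        if rng.random() < flip_rate:
            others = [l for l in label_space if l != label]
            label = others[int(rng.integers(len(others)))]
        labels[node] = label
    return labels


def save_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Serialize a bundle: edges.tsv, regulators.txt, planted_partition.tsv,
    labels.tsv, spec.json."""
    from . import netio  # local import to avoid a cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    netio.write_edge_list(bundle.network, outdir / "edges.tsv")
    (outdir / "regulators.txt").write_text(
        "".join(f"{gene}\n" for gene in sorted(bundle.regulator_ids)),
        encoding="utf-8",
    )
    with open(outdir / "planted_partition.tsv", "wt", encoding="utf-8") as handle:
        handle.write("node\tmodule\n")
        for node in sorted(bundle.planted_partition.assignment):
            handle.write(
                f"{node}\t{bundle.planted_partition.assignment[node]}\n"
            )
    with open(outdir / "labels.tsv", "wt", encoding="utf-8") as handle:
        handle.write("node\tlabel\n")
        for node in sorted(bundle.labels):
            handle.write(f"{node}\t{bundle.labels[node]}\n")
    (outdir / "spec.json").write_text(
        json.dumps(asdict(bundle.spec), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
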