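"""Interaction-network I/O and basic graph queries.

Networks are plain :class:`networkx.Graph` objects with string node IDs —
simple, undirected, unweighted. Interaction type (physical / genetic /
predicted) is deliberately not modelled: the analysis pools all evidence into
a single edge, matching how the background interactome is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentSummary:
    """Connected-component sizes (descending) and the largest component.

    Among equally large components the one containing the lexicographically
    smallest node is reported as largest.
    """

    component_sizes: tuple[int, ...]
    largest_members: frozenset[str]

    @property
    def largest_size(self) -> int:
        return self.component_sizes[0] if self.component_sizes else 0


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected edge list (two tab-separated ID columns).

    Extra columns are ignored, ``#`` lines are comments, duplicate and
    reversed-duplicate edges collapse, and self-loops are dropped with a
    warning (a gene trivially "interacts" with itself). Nodes only appear
    through their edges, so the format cannot carry isolated nodes.
    """
    graph = nx.Graph()
    with open(path, "rt", encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {line_number}: expected two node IDs, "
                    f"got {line!r}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                logger.warning(
                    "%s: line %d: dropping self-loop on %r", path, line_number, u
                )
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    return graph


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write edges as sorted two-column TSV (deterministic byte output)."""
    pairs = sorted(tuple(sorted(edge)) for edge in net.edges())
    with open(path, "wt", encoding="utf-8") as handle:
        for u, v in pairs:
            handle.write(f"{u}\t{v}\n")


def induced_subgraph(net: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph on ``genes``: their mutual edges, absentees kept as isolates.

    Keeping genes missing from the background as isolated nodes preserves the
    screen's full hit list in the component accounting (a hit with no known
    interactions still counts in the denominator of "k of n connected").
    """
    genes = set(genes)
    sub = nx.Graph()
    sub.add_nodes_from(genes)
    sub.add_edges_from(
        (u, v) for u, v in net.edges() if u in genes and v in genes
    )
    return sub


def connected_components(net: nx.Graph) -> ComponentSummary:
    """Component size spectrum plus members of the largest component."""
    components = [set(c) for c in nx.connected_components(net)]
    if not components:
        return ComponentSummary(component_sizes=(), largest_members=frozenset())
    components.sort(key=lambda c: (-len(c), min(c)))
    sizes = tuple(len(c) for c in components)
    return ComponentSummary(
        component_sizes=sizes, largest_members=frozenset(components[0])
    )


def largest_component(net: nx.Graph) -> nx.Graph:
    """Copy of the largest connected component (ties broken as above)."""
    summary = connected_components(net)
    return net.subgraph(summary.largest_members).copy()


def edge_density(net: nx.Graph) -> float:
    """Fraction of realised unordered node pairs, |E| / (n choose 2)."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("edge density requires at least 2 nodes")
    return nx.density(net)


def write_component_summary(net: nx.Graph, path: str | Path) -> None:
    """TSV with one row per component: component_id, size, members."""
    components = [set(c) for c in nx.connected_components(net)]
    components.sort(key=lambda c: (-len(c), min(c)))
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("component_id\tsize\tmembers\n")
        for index, members in enumerate(components):
            handle.write(
                f"{index}\t{len(members)}\t{','.join(sorted(members))}\n"
            )


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping alternate IDs (e.g. gene names) to node IDs."""
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t") if f.strip()]
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {line_number}: expected alias and target ID"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def apply_aliases(ids: Iterable[str], aliases: Mapping[str, str]) -> set[str]:
    """Translate IDs through an alias map; unmapped IDs pass through."""
    return {aliases.get(i, i) for i in ids}
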