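"""Modularity and modularity maximization.

Module structure is scored with undirected Newman–Girvan modularity

    Q = sum_s ( e_ss - a_s^2 )

where ``e_ss`` is the fraction of edges falling inside module ``s`` and
``a_s`` the fraction of edge endpoints attached to ``s``. Each edge counts
once; there is no resolution parameter. Three maximizers are provided:

* :func:`maximize_modularity_sa` — simulated annealing over single-node
  reassignments plus collective merge/split moves (the default and the one
  intended for real use);
* :func:`greedy_max_modularity` — deterministic agglomerative merging, a
  fast baseline and the optimizer of choice inside Monte Carlo nulls;
* :func:`exhaustive_max_modularity` — Bell-number enumeration of all set
  partitions, feasible to n = 10 only, serving as ground truth for the
  heuristics.

Partitions use canonical labels: modules numbered ``0..k-1`` by decreasing
size, ties broken by lexicographically smallest member, so equal groupings
compare equal regardless of how an optimizer happened to label them.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sympy.utilities.iterables import multiset_partitions

logger = logging.getLogger(__name__)

_EPS = 1e-12
_EXHAUSTIVE_LIMIT = 10


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one module."""

    assignment: Mapping[str, int]

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> list[set[str]]:
        """Module member sets ordered by module index."""
        groups: dict[int, set[str]] = {}
        for node, module in self.assignment.items():
            groups.setdefault(module, set()).add(node)
        return [groups[m] for m in sorted(groups)]

    def canonical(self) -> "Partition":
        return Partition(canonical_labels(self.assignment))


def canonical_labels(assignment: Mapping[str, int]) -> dict[str, int]:
    """Relabel modules 0..k-1 by decreasing size, ties by smallest member."""
    groups: dict[int, list[str]] = {}
    for node, module in assignment.items():
        groups.setdefault(module, []).append(node)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    relabel = {node: index for index, group in enumerate(ordered) for node in group}
    return {node: relabel[node] for node in assignment}


@dataclass(frozen=True)
class ModularityResult:
    """Best-found partition with its exactly recomputed Q and optimizer log."""

    partition: Partition
    Q: float
    trace: tuple[dict, ...] = ()
    seed: int | None = None


def _as_assignment(partition: Partition | Mapping[str, int]) -> Mapping[str, int]:
    return partition.assignment if isinstance(partition, Partition) else partition


def modularity(net: nx.Graph, partition: Partition | Mapping[str, int]) -> float:
    """Newman–Girvan modularity of a partition; 0 for one-module partitions."""
    assignment = _as_assignment(partition)
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless network")
    if set(assignment) != set(net.nodes):
        raise ValueError("partition must assign every network node exactly once")
    within: Counter = Counter()
    endpoint: Counter = Counter()
    for u, v in net.edges():
        if assignment[u] == assignment[v]:
            within[assignment[u]] += 1
    for node, degree in net.degree():
        endpoint[assignment[node]] += degree
    two_m = 2.0 * m
    return float(
        sum(
            within[module] / m - (endpoint[module] / two_m) ** 2
            for module in set(assignment.values())
        )
    )


def _require_edges(net: nx.Graph) -> None:
    if net.number_of_edges() == 0:
        raise ValueError("modularity optimization requires at least one edge")


def exhaustive_max_modularity(net: nx.Graph) -> ModularityResult:
    """Global optimum by enumerating every set partition (n <= 10).

    Bell(10) = 115975 partitions is the practical ceiling; beyond that the
    enumeration blows up combinatorially and the call is refused.
    """
    _require_edges(net)
    nodes = sorted(net.nodes)
    if len(nodes) > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive search limited to {_EXHAUSTIVE_LIMIT} nodes, "
            f"got {len(nodes)}"
        )
    m = net.number_of_edges()
    edges = [tuple(e) for e in net.edges()]
    degrees = dict(net.degree())
    two_m = 2.0 * m

    best_q = -math.inf
    best_assignment: dict[str, int] | None = None
    for blocks in multiset_partitions(nodes):
        assignment = {
            node: index for index, block in enumerate(blocks) for node in block
        }
        within: Counter = Counter()
        for u, v in edges:
            if assignment[u] == assignment[v]:
                within[assignment[u]] += 1
        endpoint: Counter = Counter()
        for node, degree in degrees.items():
            endpoint[assignment[node]] += degree
        q = sum(
            within[index] / m - (endpoint[index] / two_m) ** 2
            for index in range(len(blocks))
        )
        if q > best_q + _EPS:
            best_q = q
            best_assignment = assignment
    assert best_assignment is not None
    partition = Partition(canonical_labels(best_assignment))
    return ModularityResult(partition=partition, Q=modularity(net, partition))


def greedy_max_modularity(net: nx.Graph) -> ModularityResult:
    """Deterministic agglomerative maximization.

    Starts from singleton modules and repeatedly merges the connected pair of
    modules with the largest modularity gain (ties broken lexicographically by
    the smallest member of each module), tracking the best partition seen
    along the whole merge path.
    """
    _require_edges(net)
    m = net.number_of_edges()
    two_m2 = 2.0 * m * m

    # Communities keyed by their lexicographically smallest member.
    members: dict[str, set[str]] = {node: {node} for node in net.nodes}
    degree_sum: dict[str, float] = {node: float(d) for node, d in net.degree()}
    between: dict[str, Counter] = {node: Counter() for node in net.nodes}
    for u, v in net.edges():
        between[u][v] += 1
        between[v][u] += 1

    q = -sum((d / (2.0 * m)) ** 2 for d in degree_sum.values())
    best_q = q
    best_assignment = {
        node: index for index, key in enumerate(sorted(members)) for node in members[key]
    }

    while True:
        best_gain = -math.inf
        best_pair: tuple[str, str] | None = None
        for r in sorted(members):
            for s in sorted(between[r]):
                if s <= r or between[r][s] == 0:
                    continue
                gain = between[r][s] / m - degree_sum[r] * degree_sum[s] / two_m2
                if gain > best_gain + _EPS:
                    best_gain = gain
                    best_pair = (r, s)
        if best_pair is None:
            break
        r, s = best_pair
        members[r] |= members.pop(s)
        degree_sum[r] += degree_sum.pop(s)
        s_links = between.pop(s)
        for t, count in s_links.items():
            if t == r:
                continue
            between[r][t] += count
            between[t][r] += count
            del between[t][s]
        between[r].pop(s, None)
        q += best_gain
        if q > best_q + _EPS:
            best_q = q
            best_assignment = {
                node: index
                for index, key in enumerate(sorted(members))
                for node in members[key]
            }

    partition = Partition(canonical_labels(best_assignment))
    return ModularityResult(partition=partition, Q=modularity(net, partition))


@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling parameters for :func:`maximize_modularity_sa`.

    The initial temperature is set from a sample of proposed moves so that
    roughly ``target_accept`` of the initially worsening moves would be
    accepted; cooling is geometric. Each temperature performs ``n^2``
    single-node moves and ``n`` collective (merge/split) moves unless
    overridden. A temperature counts as *stale* only once the chain is
    effectively frozen (fraction of accepted moves below ``freeze_accept``)
    and the best modularity did not improve; the run stops after
    ``stale_limit`` consecutive stale temperatures, with ``max_sweeps`` as a
    hard guard. Each restart's best partition gets a deterministic
    zero-temperature refinement pass before restarts are compared.
    """

    cooling: float = 0.95
    target_accept: float = 0.5
    node_moves: int | None = None
    collective_moves: int | None = None
    stale_limit: int = 5
    freeze_accept: float = 0.05
    restarts: int = 3
    max_sweeps: int = 500


DEFAULT_SCHEDULE = AnnealSchedule()


def maximize_modularity_sa(
    net: nx.Graph,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> ModularityResult:
    """Maximize modularity by simulated annealing.

    Moves are single-node reassignments to a neighbouring module (or a fresh
    singleton module) plus collective proposals that merge two modules or
    split one by a random bisection; acceptance is Metropolis on the
    modularity change. The best partition over all restarts is returned,
    never worse than the trivial one-module partition (Q = 0). Identical
    ``seed`` (and schedule) reproduces the result exactly.

    The caller must pass a connected graph — restrict to the largest
    component first (see :func:`hsnet.netio.largest_component`).
    """
    _require_edges(net)
    if not nx.is_connected(net):
        raise ValueError(
            "simulated annealing expects a connected graph; restrict the "
            "input to its largest component first"
        )
    schedule = schedule or DEFAULT_SCHEDULE
    nodes = sorted(net.nodes)
    n = len(nodes)
    index = {node: position for position, node in enumerate(nodes)}
    adjacency = [
        [index[neighbor] for neighbor in sorted(net.neighbors(node))]
        for node in nodes
    ]
    degree = [float(len(neighbors)) for neighbors in adjacency]
    m = float(net.number_of_edges())
    node_moves = schedule.node_moves if schedule.node_moves is not None else n * n
    collective_moves = (
        schedule.collective_moves if schedule.collective_moves is not None else n
    )

    rng = np.random.default_rng(seed)
    trace: list[dict] = []

    # One-module baseline: Q = 0, always attainable.
    global_best_q = 0.0
    global_best = [0] * n

    for restart in range(schedule.restarts):
        state = _AnnealState(n, adjacency, degree, m)
        t0 = state.estimate_temperature(rng, schedule.target_accept)
        temperature = t0
        best_q = state.q
        best = list(state.community)
        stale = 0
        sweep = 0
        while stale < schedule.stale_limit and sweep < schedule.max_sweeps:
            improved = False
            accepted = 0
            for _ in range(node_moves):
                if state.node_move(rng, temperature):
                    accepted += 1
                    if state.q > best_q + _EPS:
                        best_q = state.q
                        best = list(state.community)
                        improved = True
            for _ in range(collective_moves):
                if state.collective_move(rng, temperature):
                    accepted += 1
                    if state.q > best_q + _EPS:
                        best_q = state.q
                        best = list(state.community)
                        improved = True
            frozen = accepted < schedule.freeze_accept * (
                node_moves + collective_moves
            )
            if improved:
                stale = 0
            elif frozen:
                stale += 1
            sweep += 1
            trace.append(
                {
                    "restart": restart,
                    "sweep": sweep,
                    "temperature": temperature,
                    "best_Q": best_q,
                }
            )
            temperature *= schedule.cooling
        best = _zero_temperature_refine(adjacency, degree, m, best)
        best_q = _assignment_q(adjacency, degree, m, best)
        if best_q > global_best_q + _EPS:
            global_best_q = best_q
            global_best = best

    assignment = {nodes[i]: global_best[i] for i in range(n)}
    partition = Partition(canonical_labels(assignment))
    exact_q = modularity(net, partition)
    return ModularityResult(
        partition=partition, Q=exact_q, trace=tuple(trace), seed=seed
    )


class _AnnealState:
    """Mutable annealing state with O(degree) incremental Q updates."""

    def __init__(
        self,
        n: int,
        adjacency: Sequence[Sequence[int]],
        degree: Sequence[float],
        m: float,
    ) -> None:
        self.n = n
        self.adjacency = adjacency
        self.degree = degree
        self.m = m
        # Start from singletons: within-module edge fraction is zero.
        self.community = list(range(n))
        self.members: dict[int, set[int]] = {i: {i} for i in range(n)}
        self.degree_sum: dict[int, float] = {i: degree[i] for i in range(n)}
        self.next_label = n
        self.q = -sum((d / (2.0 * m)) ** 2 for d in degree)

    # -- move proposals -------------------------------------------------

    def _node_move_proposal(self, rng: np.random.Generator):
        v = int(rng.integers(self.n))
        current = self.community[v]
        neighbor_counts: Counter = Counter(
            self.community[u] for u in self.adjacency[v]
        )
        candidates = sorted(c for c in neighbor_counts if c != current)
        if len(self.members[current]) > 1:
            candidates.append(-1)  # fresh singleton module
        if not candidates:
            return None
        target = candidates[int(rng.integers(len(candidates)))]
        k_v = self.degree[v]
        to_current = neighbor_counts.get(current, 0)
        to_target = neighbor_counts.get(target, 0) if target != -1 else 0
        target_degree = self.degree_sum.get(target, 0.0) if target != -1 else 0.0
        delta = (to_target - to_current) / self.m - k_v * (
            target_degree - (self.degree_sum[current] - k_v)
        ) / (2.0 * self.m * self.m)
        return v, current, target, delta

    def node_move(self, rng: np.random.Generator, temperature: float) -> bool:
        proposal = self._node_move_proposal(rng)
        if proposal is None:
            return False
        v, current, target, delta = proposal
        if not _metropolis(delta, temperature, rng):
            return False
        if target == -1:
            target = self.next_label
            self.next_label += 1
            self.members[target] = set()
            self.degree_sum[target] = 0.0
        self.members[current].discard(v)
        self.degree_sum[current] -= self.degree[v]
        if not self.members[current]:
            del self.members[current]
            del self.degree_sum[current]
        self.members[target].add(v)
        self.degree_sum[target] += self.degree[v]
        self.community[v] = target
        self.q += delta
        return True

    def _edges_between(self, group_a: set[int], group_b: set[int]) -> int:
        if len(group_a) > len(group_b):
            group_a, group_b = group_b, group_a
        return sum(
            1 for v in group_a for u in self.adjacency[v] if u in group_b
        )

    def collective_move(self, rng: np.random.Generator, temperature: float) -> bool:
        labels = sorted(self.members)
        if rng.random() < 0.5:
            return self._merge_move(labels, rng, temperature)
        return self._split_move(labels, rng, temperature)

    def _merge_move(self, labels, rng, temperature) -> bool:
        if len(labels) < 2:
            return False
        pick = rng.choice(len(labels), size=2, replace=False)
        r, s = labels[int(pick[0])], labels[int(pick[1])]
        e_rs = self._edges_between(self.members[r], self.members[s])
        delta = e_rs / self.m - self.degree_sum[r] * self.degree_sum[s] / (
            2.0 * self.m * self.m
        )
        if not _metropolis(delta, temperature, rng):
            return False
        for v in self.members[s]:
            self.community[v] = r
        self.members[r] |= self.members.pop(s)
        self.degree_sum[r] += self.degree_sum.pop(s)
        self.q += delta
        return True

    def _split_move(self, labels, rng, temperature) -> bool:
        splittable = [label for label in labels if len(self.members[label]) >= 2]
        if not splittable:
            return False
        label = splittable[int(rng.integers(len(splittable)))]
        group = sorted(self.members[label])
        mask = rng.random(len(group)) < 0.5
        part_b = {v for v, flag in zip(group, mask) if flag}
        if not part_b or len(part_b) == len(group):
            return False
        part_a = set(group) - part_b
        e_ab = self._edges_between(part_a, part_b)
        d_a = sum(self.degree[v] for v in part_a)
        d_b = sum(self.degree[v] for v in part_b)
        delta = -(e_ab / self.m - d_a * d_b / (2.0 * self.m * self.m))
        if not _metropolis(delta, temperature, rng):
            return False
        fresh = self.next_label
        self.next_label += 1
        for v in part_b:
            self.community[v] = fresh
        self.members[label] = part_a
        self.members[fresh] = part_b
        self.degree_sum[label] = d_a
        self.degree_sum[fresh] = d_b
        self.q += delta
        return True

    # -- temperature calibration ----------------------------------------

    def estimate_temperature(
        self, rng: np.random.Generator, target_accept: float
    ) -> float:
        """Temperature at which the median worsening move accepts at
        ``target_accept`` probability (sampled, not applied)."""
        losses = []
        for _ in range(max(50, 2 * self.n)):
            proposal = self._node_move_proposal(rng)
            if proposal is not None and proposal[3] < 0:
                losses.append(-proposal[3])
        if not losses:
            return 0.05
        return float(np.median(losses) / math.log(1.0 / target_accept))


def _assignment_q(
    adjacency: Sequence[Sequence[int]],
    degree: Sequence[float],
    m: float,
    community: Sequence[int],
) -> float:
    within: Counter = Counter()
    endpoint: Counter = Counter()
    for v, neighbors in enumerate(adjacency):
        endpoint[community[v]] += degree[v]
        for u in neighbors:
            if u > v and community[u] == community[v]:
                within[community[v]] += 1
    return sum(
        within[c] / m - (endpoint[c] / (2.0 * m)) ** 2 for c in set(community)
    )


def _zero_temperature_refine(
    adjacency: Sequence[Sequence[int]],
    degree: Sequence[float],
    m: float,
    community: Sequence[int],
) -> list[int]:
    """Deterministic hill climb: move each node to its best community
    (neighbouring community or a fresh singleton) until no move improves Q."""
    comm = list(community)
    n = len(comm)
    degree_sum: Counter = Counter()
    for v in range(n):
        degree_sum[comm[v]] += degree[v]
    next_label = max(comm) + 1
    improved = True
    passes = 0
    while improved and passes < n + 1:
        improved = False
        passes += 1
        for v in range(n):
            current = comm[v]
            counts = Counter(comm[u] for u in adjacency[v])
            k_v = degree[v]
            to_current = counts.get(current, 0)
            best_delta = _EPS
            best_target = current
            candidates = sorted(c for c in counts if c != current)
            if degree_sum[current] > k_v:  # fresh singleton is a real move
                candidates.append(-1)
            for target in candidates:
                to_target = counts.get(target, 0) if target != -1 else 0
                target_degree = degree_sum[target] if target != -1 else 0.0
                delta = (to_target - to_current) / m - k_v * (
                    target_degree - (degree_sum[current] - k_v)
                ) / (2.0 * m * m)
                if delta > best_delta:
                    best_delta = delta
                    best_target = target
            if best_target != current:
                if best_target == -1:
                    best_target = next_label
                    next_label += 1
                degree_sum[current] -= k_v
                degree_sum[best_target] += k_v
                comm[v] = best_target
                improved = True
    return comm


def _metropolis(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    if delta >= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < math.exp(delta / temperature))


def write_partition(
    partition: Partition, path, net: nx.Graph | None = None
) -> None:
    """Partition as TSV: node, module, module_size."""
    sizes = Counter(partition.assignment.values())
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("node\tmodule\tmodule_size\n")
        for node in sorted(partition.assignment):
            module = partition.assignment[node]
            handle.write(f"{node}\t{module}\t{sizes[module]}\n")


def write_trace(result: ModularityResult, path) -> None:
    """Optimizer iteration log as TSV (restart, sweep, temperature, best Q)."""
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("restart\tsweep\ttemperature\tbest_Q\n")
        for entry in result.trace:
            handle.write(
                f"{entry['restart']}\t{entry['sweep']}\t"
                f"{entry['temperature']:.8g}\t{entry['best_Q']:.8g}\n"
            )
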