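"""Agreement between network modules and tissue-induction labels.

The claim that interaction-derived modules "line up" with tissue-selective
reporter-induction patterns is quantified with the adjusted Rand index (ARI)
between the module assignment and the per-gene tissue category, a
label-permutation test for its significance, and purity (the fraction of
genes whose tissue category is the majority category of their module) as a
descriptive companion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .community import Partition
from .nullmodels import empirical_p_value


@dataclass(frozen=True)
class LabeledPartition:
    """A module assignment and a label per node, over the same node set."""

    assignment: Mapping[str, int]
    labels: Mapping[str, Hashable]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(self.labels):
            raise ValueError("assignment and labels must cover the same nodes")

    @classmethod
    def from_partition(
        cls, partition: Partition, labels: Mapping[str, Hashable]
    ) -> "LabeledPartition":
        return cls(assignment=dict(partition.assignment), labels=dict(labels))


@dataclass(frozen=True)
class AgreementResult:
    """ARI and purity of modules vs labels, with a permutation p-value."""

    ari: float
    purity: float
    p_value: float
    n_permutations: int
    seed: int


def adjusted_rand_index(
    a: Mapping[str, Hashable], b: Mapping[str, Hashable]
) -> float:
    """Chance-corrected pair-counting agreement between two groupings.

    1 for identical groupings, about 0 for independent ones; symmetric in
    its arguments and invariant to how either grouping labels its groups.
    """
    if set(a) != set(b):
        raise ValueError("groupings must cover the same item set")
    items = sorted(a)
    if len(items) < 2:
        raise ValueError("ARI needs at least 2 items")
    labels_a = [a[i] for i in items]
    labels_b = [b[i] for i in items]
    return float(adjusted_rand_score(labels_a, labels_b))


def purity(
    assignment: Mapping[str, int], labels: Mapping[str, Hashable]
) -> float:
    """Fraction of nodes whose label is the majority label of their module."""
    if set(assignment) != set(labels):
        raise ValueError("assignment and labels must cover the same nodes")
    if not assignment:
        raise ValueError("purity of an empty assignment is undefined")
    per_module: dict[int, Counter] = {}
    for node, module in assignment.items():
        per_module.setdefault(module, Counter())[labels[node]] += 1
    majority = sum(counts.most_common(1)[0][1] for counts in per_module.values())
    return majority / len(assignment)


def module_label_agreement(
    labeled: LabeledPartition,
    n_permutations: int = 999,
    seed: int = 0,
) -> AgreementResult:
    """ARI between modules and labels with a label-permutation null.

    Labels are shuffled across nodes ``n_permutations`` times; the p-value is
    the pseudocounted fraction of permutations whose ARI reaches the observed
    one. Requires at least two modules and two distinct labels (otherwise
    agreement is vacuous).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    assignment = dict(labeled.assignment)
    labels = dict(labeled.labels)
    if len(set(assignment.values())) < 2:
        raise ValueError("need at least 2 modules")
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 distinct labels")

    items = sorted(assignment)
    module_vector = [assignment[i] for i in items]
    label_vector = [labels[i] for i in items]
    observed = float(adjusted_rand_score(module_vector, label_vector))

    rng = np.random.default_rng(seed)
    label_array = np.array(label_vector, dtype=object)
    samples = []
    for _ in range(n_permutations):
        permuted = label_array[rng.permutation(len(label_array))]
        samples.append(float(adjusted_rand_score(module_vector, permuted)))
    return AgreementResult(
        ari=observed,
        purity=purity(assignment, labels),
        p_value=empirical_p_value(observed, samples),
        n_permutations=n_permutations,
        seed=seed,
    )


def write_agreement_table(labeled: LabeledPartition, path) -> None:
    """Per-node TSV: node, module, label, whether label is module majority."""
    per_module: dict[int, Counter] = {}
    for node, module in labeled.assignment.items():
        per_module.setdefault(module, Counter())[labeled.labels[node]] += 1
    majority = {
        module: counts.most_common(1)[0][0]
        for module, counts in per_module.items()
    }
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("node\tmodule\tlabel\tmajority_match\n")
        for node in sorted(labeled.assignment):
            module = labeled.assignment[node]
            label = labeled.labels[node]
            match = int(label == majority[module])
            handle.write(f"{node}\t{module}\t{label}\t{match}\n")
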