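"""End-to-end analysis: tables -> subnetwork -> modules -> nulls -> concordance.

:func:`run_hsn_analysis` reproduces the network half of the heat-shock
regulatory network study as one reproducible run: it loads the screen tables,
obtains a background interactome (a user-supplied edge list or the synthetic
generator), induces the regulator subnetwork, summarizes its components,
detects modules on the largest component, attaches Monte Carlo significance
(rewiring null for modularity, random gene sets for interaction density),
and quantifies module/tissue-pattern agreement. Everything is driven by an
:class:`AnalysisConfig` with explicit seeds, and the report is a plain dict
serialized to JSON so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import yaml

from . import __version__, netio, tables
from .community import (
    AnnealSchedule,
    ModularityResult,
    greedy_max_modularity,
    maximize_modularity_sa,
    write_partition,
    write_trace,
)
from .concordance import LabeledPartition, module_label_agreement, write_agreement_table
from .nullmodels import (
    density_enrichment,
    modularity_null_pvalue,
    write_null_samples,
)
from .synthetic import PlantedSpec, generate_planted_network

logger = logging.getLogger(__name__)

#: Hamming-distance anchors used to collapse observed tissue categories onto
#: the three planted modules when simulating around a real gene table.
PATTERN_ANCHORS = ("SI-", "--M", "-I-")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully explicit configuration of one analysis run."""

    gene_table: str = "packaged:negative"
    edge_list: str = "synthetic"
    planted: Mapping[str, Any] = field(default_factory=dict)
    optimizer: str = "sa"
    null_optimizer: str = "greedy"
    null_realizations: int = 999
    swaps_per_edge: int = 10
    null_model: str = "degree"
    enrichment_samples: int = 999
    agreement_permutations: int = 999
    sa_restarts: int = 3
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a flat YAML mapping (``planted:`` may nest)."""
        with open(path, "rt", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["planted"] = dict(self.planted)
        return out


def _load_gene_records(config: AnalysisConfig) -> list[tables.GeneRecord]:
    if config.gene_table == "packaged:negative":
        return tables.load_negative_regulators()
    if config.gene_table == "packaged:positive":
        return tables.load_positive_regulators()
    return tables.read_gene_table(config.gene_table)


def pattern_modules(
    records: list[tables.GeneRecord],
    anchors: tuple[str, ...] = PATTERN_ANCHORS,
) -> dict[str, int]:
    """Assign each gene to the anchor category nearest its tissue pattern.

    Used to plant interaction modules that follow the observed tissue-pattern
    classes when simulating a background for a real gene table: each gene
    joins the anchor with minimal Hamming distance to its S/I/M flags (ties
    to the earliest anchor).
    """
    assignment = {}
    for record in records:
        if record.pattern is None:
            raise ValueError(f"record {record.cosmid} carries no tissue pattern")
        category = record.pattern.category
        distances = [
            sum(x != y for x, y in zip(category, anchor)) for anchor in anchors
        ]
        assignment[record.cosmid] = distances.index(min(distances))
    return assignment


def _obtain_network(
    config: AnalysisConfig, records: list[tables.GeneRecord]
):
    """Return (background graph, regulator labels, bundle-or-None)."""
    if config.edge_list != "synthetic":
        path = Path(config.edge_list)
        if not path.exists():
            raise FileNotFoundError(
                f"edge list {path} not found; pass a two-column TSV or "
                f"'synthetic' to simulate a background"
            )
        return netio.read_edge_list(path), None
    overrides = dict(config.planted)
    overrides.setdefault("n_regulators", len(records))
    overrides.setdefault("seed", config.seed)
    have_patterns = all(r.pattern is not None for r in records)
    planted_assignment = None
    if have_patterns:
        planted_assignment = pattern_modules(records)
        overrides.setdefault(
            "n_modules", len(set(planted_assignment.values()))
        )
    spec = PlantedSpec(**overrides)
    if planted_assignment is not None and (
        len(set(planted_assignment.values())) != spec.n_modules
    ):
        planted_assignment = None  # explicit module count wins
    bundle = generate_planted_network(
        spec,
        seed=spec.seed,
        regulator_ids=[r.cosmid for r in records],
        planted_assignment=planted_assignment,
    )
    return bundle.network, bundle


def _detect_modules(
    graph, config: AnalysisConfig
) -> ModularityResult:
    if config.optimizer == "greedy":
        return greedy_max_modularity(graph)
    schedule = AnnealSchedule(restarts=config.sa_restarts)
    return maximize_modularity_sa(graph, schedule=schedule, seed=config.seed)


def run_hsn_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    t_start = time.perf_counter()
    logger.info("analysis starting: seed=%d config=%s", config.seed, config.to_dict())

    def stage(name: str):
        logger.info("[%s] t=%.1fs", name, time.perf_counter() - t_start)

    stage("tables")
    try:
        records = _load_gene_records(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'tables' failed: {exc}") from exc
    positives = tables.load_positive_regulators()
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "provenance": {
            "hsnet_version": __version__,
            "networkx_version": nx.__version__,
            "seed": config.seed,
        },
    }
    gene_block: dict[str, Any] = {
        "n_records": len(records),
        "n_negative": sum(r.sign == tables.SIGN_NEGATIVE for r in records),
        "n_positive_packaged": len(positives),
        "by_class": _tally(r.functional_class for r in records),
    }
    if all(r.pattern is not None for r in records):
        gene_block["by_pattern"] = {
            k: v for k, v in tables.pattern_class_sizes(records).items() if v
        }
        muscle_only = tables.filter_by_pattern(
            records, tables.TissuePattern(False, False, True)
        )
        gene_block["muscle_only_tric_cct"] = sum(
            "CCT/TRiC" in r.description for r in muscle_only
        )
    report["genes"] = gene_block

    stage("network")
    try:
        background, bundle = _obtain_network(config, records)
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc
    geneset = [r.cosmid for r in records]
    subnetwork = netio.induced_subgraph(background, geneset)
    summary = netio.connected_components(subnetwork)
    report["components"] = {
        "sizes": list(summary.component_sizes),
        "largest_size": summary.largest_size,
        "largest_members": sorted(summary.largest_members),
    }

    stage("modules")
    giant = netio.largest_component(subnetwork)
    if giant.number_of_edges() == 0:
        raise RuntimeError(
            "stage 'modules' failed: the regulator subnetwork has no edges; "
            "check that gene IDs match the edge-list node IDs"
        )
    result = _detect_modules(giant, config)
    unassigned = sorted(set(subnetwork.nodes) - set(giant.nodes))
    report["modules"] = {
        "n_modules": result.partition.n_modules,
        "Q": result.Q,
        "optimizer": config.optimizer,
        "assignment": {
            node: module
            for node, module in sorted(result.partition.assignment.items())
        },
        "unassigned": unassigned,
    }

    stage("modularity_null")
    null = modularity_null_pvalue(
        giant,
        n_realizations=config.null_realizations,
        seed=config.seed,
        optimizer=config.null_optimizer,
        swaps_per_edge=config.swaps_per_edge,
        null_model=config.null_model,
    )
    report["modularity_null"] = {
        "observed_Q": null.observed,
        "p_value": null.p_value,
        "n_realizations": null.n_realizations,
        "optimizer": config.null_optimizer,
        "null_model": config.null_model,
    }

    stage("density_enrichment")
    enrichment = density_enrichment(
        background,
        geneset,
        n_samples=config.enrichment_samples,
        seed=config.seed,
    )
    report["density_enrichment"] = {
        "observed_density": enrichment.observed_density,
        "background_density": enrichment.background_density,
        "ratio": enrichment.ratio,
        "p_value": enrichment.null.p_value,
        "n_samples": enrichment.null.n_realizations,
    }

    stage("concordance")
    labels = _node_labels(records, bundle, giant)
    agreement_block: dict[str, Any] | None = None
    if labels is not None:
        labeled = LabeledPartition(
            assignment=dict(result.partition.assignment), labels=labels
        )
        try:
            agreement = module_label_agreement(
                labeled,
                n_permutations=config.agreement_permutations,
                seed=config.seed,
            )
            agreement_block = {
                "ari": agreement.ari,
                "purity": agreement.purity,
                "p_value": agreement.p_value,
                "n_permutations": agreement.n_permutations,
            }
        except ValueError as exc:
            logger.warning("module/label agreement skipped: %s", exc)
    report["agreement"] = agreement_block

    report["reporter_concordance"] = run_reporter_concordance()

    if config.outdir is not None:
        _write_sidecars(config, report, result, null, labeled if labels else None)
    logger.info("analysis finished in %.1fs", time.perf_counter() - t_start)
    return report


def _node_labels(records, bundle, giant) -> dict[str, str] | None:
    """Tissue labels for the module-bearing nodes: observed S/I/M categories
    when the gene table carries them, else the synthetic bundle's labels."""
    if all(r.pattern is not None for r in records):
        by_cosmid = {r.cosmid: r.pattern.category for r in records}
        return {node: by_cosmid[node] for node in giant.nodes if node in by_cosmid}
    if bundle is not None:
        return {node: bundle.labels[node] for node in giant.nodes}
    return None


def _tally(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for value in values:
        out[value] = out.get(value, 0) + 1
    return dict(sorted(out.items()))


#: Reporter column pairs compared in the three-reporter analysis, keyed by a
#: short name: the muscle comparison between the hsp70 and hsp16.2 reporters
#: and the intestine comparisons among hsp70, ckb-2 and hsp16.2.
REPORTER_PAIRS: dict[str, tuple[str, str]] = {
    "muscle_hsp70_vs_hsp16": ("hsp70_M", "hsp16_M"),
    "intestine_hsp70_vs_ckb2": ("hsp70_I", "ckb2_I"),
    "intestine_hsp70_vs_hsp16": ("hsp70_I", "hsp16_I"),
    "intestine_ckb2_vs_hsp16": ("ckb2_I", "hsp16_I"),
}


def run_reporter_concordance(path: str | Path | None = None) -> dict:
    """Pairwise reporter concordance counts plus per-column inducer tallies."""
    rows = (
        tables.load_reporter_table()
        if path is None
        else tables.read_reporter_table(path)
    )
    pairs = {}
    for name, (col_a, col_b) in REPORTER_PAIRS.items():
        counts = tables.concordance_counts(rows, col_a, col_b)
        pairs[name] = {
            "both": counts.both,
            "neither": counts.neither,
            "discordant": counts.discordant,
        }
    inducers = {
        column: sum(getattr(row, column) for row in rows)
        for column in tables.REPORTER_FLAG_COLUMNS
    }
    return {"n_genes": len(rows), "pairs": pairs, "inducers": inducers}


def _write_sidecars(config, report, result, null, labeled) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir / "report.json")
    write_partition(result.partition, outdir / "partition.tsv")
    write_trace(result, outdir / "sa_trace.tsv")
    write_null_samples(null, outdir / "null_samples.tsv")
    if labeled is not None:
        write_agreement_table(labeled, outdir / "node_concordance.tsv")
    logger.info("report and sidecars written to %s", outdir)


def write_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON serialization (sorted keys, no timestamps)."""
    with open(path, "wt", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")


def draw_module_network(
    graph,
    assignment: Mapping[str, int],
    labels: Mapping[str, str] | None = None,
    path: str | Path | None = None,
):
    """Convenience rendering: node shape by module, colour by tissue label.

    A quick-look figure, not a publication layout; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shapes = "osD^vp8h"
    categories = sorted(set((labels or {}).values())) or ["-"]
    cmap = plt.get_cmap("tab10")
    colour_of = {category: cmap(i % 10) for i, category in enumerate(categories)}

    pos = nx.spring_layout(graph, seed=0)
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx_edges(graph, pos, ax=ax, alpha=0.4)
    for module in sorted(set(assignment.values())):
        nodes = [n for n in graph.nodes if assignment.get(n) == module]
        colours = [
            colour_of[(labels or {}).get(n, categories[0])] for n in nodes
        ]
        nx.draw_networkx_nodes(
            graph,
            pos,
            nodelist=nodes,
            node_shape=shapes[module % len(shapes)],
            node_color=colours,
            node_size=180,
            ax=ax,
        )
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
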