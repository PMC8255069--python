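"""End-to-end pipeline driver.

Runs the full analysis in the canonical order -- differential
expression, co-expression modules, network centralities, equal-
frequency discretization, association-rule mining, guilt-by-association
prediction -- writing each stage's artifact plus a machine-readable run
manifest (package version, parameters, input checksums, per-stage
record counts) into an output directory. The pipeline is deterministic:
re-running on the same inputs reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import __version__
from .arm import filter_rules, generate_rules, apriori
from .coexpression import (
    adjacency,
    cut_modules,
    hierarchical_cluster,
    merge_close_modules,
    module_eigengene,
    select_beta,
    similarity,
    tom_dissimilarity,
    topological_overlap,
)
from .discretize import discretize_matrix
from .network_metrics import build_network, centrality_table, density, filter_by_degree, hub_table
from .prediction import predict_functions
from .preprocess import (
    differential_expression,
    filter_low_counts,
    log_normalized,
    select_de_genes,
    size_factors,
)

logger = logging.getLogger(__name__)

STAGES = ("preprocess_de", "coexpression", "network", "discretize", "arm", "prediction")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters, with the study defaults.

    ``beta`` may be an integer soft-threshold power or ``"auto"`` to
    pick it from the scale-free fit. ``discretize_universe`` selects the
    gene set turned into transactions: nodes of the degree-filtered
    network (default), all module genes, or all filtered genes.
    """

    counts: str | Path = ""
    metadata: str | Path = ""
    annotations: str | Path | None = None
    out_dir: str | Path = "coexrules_run"
    # preprocess / DE
    min_count: int = 10
    min_count_sample_frac: float = 0.9
    contrast: str = "attractant:control"
    fdr: float = 0.05
    min_fold: float = 2.0
    # coexpression
    beta: int | str = 12
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    merge_cut: float = 0.25
    # network
    edge_threshold: float = 0.2
    min_degree: int = 5
    hub_degree: int = 8
    # discretization / rule mining
    bins: int = 2
    discretize_universe: str = "network"
    min_support: float = 0.5
    min_confidence: float = 0.99
    min_lift: float = 2.0
    max_rule_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must lie in (0, 1]")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must lie in [0, 1]")
        if not 0 < self.edge_threshold <= 1:
            raise ValueError("edge_threshold must lie in (0, 1]")
        if self.discretize_universe not in ("network", "modules", "all"):
            raise ValueError("discretize_universe must be network|modules|all")
        if self.beta != "auto" and (not isinstance(self.beta, int) or self.beta < 1):
            raise ValueError("beta must be an integer >= 1 or 'auto'")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if ":" not in self.contrast:
            raise ValueError("contrast must look like 'attractant:control'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("counts", "metadata", "annotations", "out_dir"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out


def run_pipeline(config: PipelineConfig, cm=None, annotations=None) -> Path:
    """Execute all stages; returns the run directory.

    ``cm`` (a CountMatrix) and ``annotations`` (a DataFrame) may be
    passed directly instead of being read from the configured paths.
    Any stage failure aborts with the stage name in the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "coexrules",
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": [],
    }
    if cm is None:
        cm = cio.read_count_matrix(config.counts, config.metadata)
        manifest["inputs"][str(config.counts)] = cio.sha256_of(config.counts)
        manifest["inputs"][str(config.metadata)] = cio.sha256_of(config.metadata)
    if annotations is None and config.annotations:
        annotations = cio.read_annotations(config.annotations)
        manifest["inputs"][str(config.annotations)] = cio.sha256_of(config.annotations)

    def record(stage: str, outputs: dict[str, int]) -> None:
        manifest["stages"].append({"name": stage, "outputs": outputs})
        logger.info("stage %s done: %s", stage, outputs)

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:  # surface the failing stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage 1: filtering, normalization, differential expression
    def stage_de():
        filtered = filter_low_counts(cm, config.min_count, config.min_count_sample_frac)
        factors = size_factors(filtered)
        treatment, control = config.contrast.split(":", 1)
        de = differential_expression(filtered, (treatment, control))
        selected = sorted(select_de_genes(de, config.fdr, config.min_fold))
        de.to_csv(out / "de_results.csv", index=False)
        (out / "de_selected_genes.txt").write_text("".join(g + "\n" for g in selected))
        record(
            "preprocess_de",
            {"de_results.csv": len(de), "de_selected_genes.txt": len(selected)},
        )
        return filtered, factors

    filtered, factors = run_stage("preprocess_de", stage_de)

    # ---- stage 2: co-expression modules
    def stage_coexpression():
        expr = log_normalized(filtered, factors)
        if config.beta == "auto":
            beta, table = select_beta(expr)
        else:
            beta, table = int(config.beta), None
        s = similarity(expr)
        expr = expr.loc[s.index]  # constant genes dropped with the similarity
        a = adjacency(s, beta)
        tom = topological_overlap(a)
        dendrogram = hierarchical_cluster(tom_dissimilarity(tom))
        modules = cut_modules(
            dendrogram, tom.index, config.min_module_size, config.cut_height_quantile
        )
        modules = merge_close_modules(expr, modules, config.merge_cut)
        eigengenes = module_eigengene(expr, modules)
        cio.write_module_assignment(modules, out / "modules.tsv")
        cio.write_eigengenes(eigengenes, out / "eigengenes.tsv")
        outputs = {
            "modules.tsv": int(modules.labels.size),
            "eigengenes.tsv": int(eigengenes.values.shape[0]),
        }
        if table is not None:
            table.to_csv(out / "beta_table.csv", index=False)
            outputs["beta_table.csv"] = len(table)
        record("coexpression", outputs)
        return expr, tom, modules

    expr, tom, modules = run_stage("coexpression", stage_coexpression)

    # ---- stage 3: network and centralities
    def stage_network():
        module_genes = [g for g in tom.index if modules.labels.get(g, 0) != 0]
        subset = module_genes if module_genes else list(tom.index)
        categories = None
        if annotations is not None:
            categories = dict(zip(annotations["gene_id"], annotations["category"]))
        net = build_network(tom, config.edge_threshold, subset, categories)
        filtered_net = filter_by_degree(net, config.min_degree)
        table = centrality_table(filtered_net if filtered_net.number_of_nodes() else net)
        hubs = hub_table(table, config.hub_degree)
        table.to_csv(out / "centrality.csv")
        hubs.to_csv(out / "hub_table.csv")
        cio.write_edge_list(filtered_net, out / "edges.tsv")
        if filtered_net.number_of_nodes():
            cio.export_graphml(filtered_net, out / "network.graphml")
        summary = {
            "nodes_unfiltered": net.number_of_nodes(),
            "edges_unfiltered": net.number_of_edges(),
            "nodes": filtered_net.number_of_nodes(),
            "edges": filtered_net.number_of_edges(),
            "density": density(filtered_net)
            if filtered_net.number_of_nodes() >= 2
            else float("nan"),
        }
        pd.Series(summary).to_csv(out / "network_summary.csv", header=False)
        record(
            "network",
            {
                "centrality.csv": len(table),
                "hub_table.csv": len(hubs),
                "edges.tsv": filtered_net.number_of_edges(),
            },
        )
        return net, filtered_net

    net, filtered_net = run_stage("network", stage_network)

    # ---- stage 4: discretization
    def stage_discretize():
        if config.discretize_universe == "network" and filtered_net.number_of_nodes():
            universe = list(filtered_net.nodes)
        elif config.discretize_universe in ("network", "modules"):
            module_genes = [g for g in expr.index if modules.labels.get(g, 0) != 0]
            universe = module_genes if module_genes else list(expr.index)
        else:
            universe = list(expr.index)
        db = discretize_matrix(expr.loc[universe], config.bins)
        cio.write_transactions_basket(db, out / "transactions.basket")
        record("discretize", {"transactions.basket": len(db.transaction_ids)})
        return db

    db = run_stage("discretize", stage_discretize)

    # ---- stage 5: association-rule mining
    def stage_arm():
        itemsets = apriori(db, config.min_support, max_len=config.max_rule_len)
        rules = generate_rules(itemsets, min_confidence=config.min_confidence)
        kept = filter_rules(rules, config.min_lift)
        cio.write_rules_csv(kept, out / "rules.csv")
        record(
            "arm",
            {"rules.csv": len(kept), "rules_before_lift_filter": len(rules)},
        )
        return kept

    rules = run_stage("arm", stage_arm)

    # ---- stage 6: function prediction
    def stage_prediction():
        if annotations is None:
            predictions = []
        else:
            predictions = predict_functions(rules, annotations)
        cio.write_predictions_csv(predictions, out / "predictions.csv")
        record("prediction", {"predictions.csv": len(predictions)})

    run_stage("prediction", stage_prediction)

    cio.write_manifest(manifest, out / "manifest.json")
    return out
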