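"""End-to-end orchestration: simulate/load → DE → network → consensus → drugs.

A :class:`PipelineConfig` either points at the four input tables
(expression + groups, interactome, drug targets) or embeds a
:class:`~keygenet.simulate.SimulationConfig`; :func:`run_pipeline` executes
every stage, optionally writes all stage outputs under an output directory,
and returns a :class:`PipelineResult` whose ``manifest`` (parameters, seed,
per-stage counts) is byte-stable under a fixed configuration and seed.

A single global seed fans out to the stages by fixed offsets (simulation
uses the seed itself; the EPC Monte Carlo uses seed + 10), so adding stages
never perturbs existing ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__, io
from .containers import (
    DrugRanking,
    ExpressionMatrix,
    InvalidConfigError,
    KeyGeneSet,
)
from .centrality import run_comparison_algorithms, run_integration_algorithms
from .diffexpr import Thresholds, run_differential_expression
from .drugrank import bipartite_graph, filter_nervous_system_drugs, rank_drugs
from .integrate import intersect_key_genes, key_gene_correlation
from .netbuild import build_deg_network, extract_core, filter_interactions
from .simulate import (
    DEFAULT_DRUG_BUCKETS,
    DEGroundTruth,
    SimulationConfig,
    simulate_drug_targets,
    simulate_expression,
    simulate_interactome,
)

logger = logging.getLogger(__name__)

_EPC_SEED_OFFSET = 10


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run.

    Exactly one input mode must be set: ``simulate`` (a
    :class:`SimulationConfig`) or all four of ``expression_path``,
    ``groups_path``, ``interactome_path``, ``drugs_path``.
    """

    simulate: SimulationConfig | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    interactome_path: str | None = None
    drugs_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_score: int = 900
    min_component_size: int | None = None
    k: int = 10
    candidate_min: int = 3
    katz_alpha: float = 0.1
    epc_threshold: float = 0.5
    epc_n_reduced: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        paths = [self.expression_path, self.groups_path,
                 self.interactome_path, self.drugs_path]
        have_paths = all(p is not None for p in paths)
        if (self.simulate is None) == (not have_paths):
            raise InvalidConfigError(
                "config must set either 'simulate' or all four input paths"
            )
        if self.simulate is not None and self.simulate.rng_seed != self.seed:
            # the global seed governs everything, including the simulation
            self.simulate = SimulationConfig(
                **{**asdict(self.simulate), "rng_seed": self.seed}
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config file; keyword overrides win over file keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidConfigError("config file must contain a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("simulate"), dict):
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if isinstance(raw.get("thresholds"), dict):
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """All stage outputs of one run plus the reproducibility manifest."""

    expression: ExpressionMatrix
    ground_truth: DEGroundTruth | None
    deg_table: pd.DataFrame
    network: nx.Graph
    core: nx.Graph
    centrality_tables: list
    comparison_tables: list
    key_genes: KeyGeneSet
    correlations: dict[str, pd.DataFrame]
    drug_table: pd.DataFrame
    drug_ranking: DrugRanking | None
    manifest: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage of the pipeline under ``config``.

    With ``config.outdir`` set, all stage outputs (TSVs, GraphML, JSON
    sidecars and the manifest) are written there; partial outputs are kept
    if a later stage fails.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    truth: DEGroundTruth | None = None
    if config.simulate is not None:
        expr, truth = _stage("simulate")(simulate_expression, config.simulate)
        edges = _stage("simulate")(simulate_interactome, config.simulate, truth)
        if outdir:
            io.write_expression(expr, outdir / "expression.tsv", outdir / "groups.tsv")
            io.write_edge_list(edges, outdir / "interactome.tsv")
            truth.save(outdir / "ground_truth.json")
    else:
        expr = _stage("load")(
            io.read_expression, config.expression_path, config.groups_path
        )
        edges = _stage("load")(io.read_edge_list, config.interactome_path)

    deg_table = _stage("diffexpr")(
        run_differential_expression, expr, config.thresholds
    )
    if outdir:
        io.write_deg_table(deg_table, outdir / "deg_table.tsv")

    filtered = _stage("netbuild")(filter_interactions, edges, config.min_score)
    network = _stage("netbuild")(build_deg_network, filtered, deg_table)
    core = _stage("netbuild")(extract_core, network, config.min_component_size)
    if outdir:
        io.write_graphml(core, outdir / "core.graphml")

    tables = _stage("centrality")(
        run_integration_algorithms,
        core,
        katz_alpha=config.katz_alpha,
        epc_threshold=config.epc_threshold,
        epc_n_reduced=config.epc_n_reduced,
        epc_seed=config.seed + _EPC_SEED_OFFSET,
    )
    comparison = _stage("centrality")(run_comparison_algorithms, core)
    if outdir:
        io.write_centrality_tables(
            tables + comparison, outdir / "centrality.tsv",
            outdir / "centrality_params.json",
        )

    key = _stage("integrate")(intersect_key_genes, tables, config.k)
    correlations = (
        _stage("integrate")(key_gene_correlation, expr, key) if key.genes else {}
    )
    if outdir:
        io.write_key_genes(key, outdir / "key_genes.txt", outdir / "provenance.json")
        for group, corr in correlations.items():
            corr.to_csv(outdir / f"correlation_{group}.tsv", sep="\t")

    if config.simulate is not None:
        hubs = truth.hubs if truth else []
        non_hub_de = [g for g in (truth.de_genes if truth else []) if g not in hubs]
        # buckets needing more hits than there are hub genes are infeasible
        buckets = {h: c for h, c in DEFAULT_DRUG_BUCKETS.items() if h <= len(hubs)}
        drug_table = _stage("drugrank")(
            simulate_drug_targets, config.simulate, hubs,
            buckets=buckets, other_genes=non_hub_de,
        ) if hubs else pd.DataFrame(columns=["drug_id", "atc_code", "gene"])
        if outdir:
            io.write_drug_table(drug_table, outdir / "drug_targets.tsv")
    else:
        drug_table = _stage("load")(io.read_drug_table, config.drugs_path)

    ranking: DrugRanking | None = None
    if key.genes and len(drug_table):
        nervous = _stage("drugrank")(filter_nervous_system_drugs, drug_table)
        ranking = _stage("drugrank")(
            rank_drugs, nervous, key, config.candidate_min
        )
        if outdir:
            ranking.table.to_csv(outdir / "drug_ranking.tsv", sep="\t", index=False)
            ranking.histogram.to_csv(outdir / "drug_histogram.tsv", sep="\t")
            if len(ranking.table):
                io.write_graphml(
                    bipartite_graph(ranking), outdir / "drug_bipartite.graphml"
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "p_threshold": config.thresholds.p_threshold,
            "fc_threshold": config.thresholds.fc_threshold,
            "min_score": config.min_score,
            "min_component_size": config.min_component_size,
            "k": config.k,
            "candidate_min": config.candidate_min,
            "katz_alpha": config.katz_alpha,
            "epc_threshold": config.epc_threshold,
            "epc_n_reduced": config.epc_n_reduced,
            "simulate": asdict(config.simulate) if config.simulate else None,
        },
        "counts": {
            "n_genes": len(expr.gene_ids),
            "n_samples": len(expr.values.columns),
            "n_deg": int(deg_table["is_deg"].sum()),
            "n_deg_up": int((deg_table["direction"] == "up").sum()),
            "n_deg_down": int((deg_table["direction"] == "down").sum()),
            "network_nodes": network.number_of_nodes(),
            "network_edges": network.number_of_edges(),
            "core_nodes": core.number_of_nodes(),
            "core_edges": core.number_of_edges(),
            "n_key_genes": len(key),
            "key_genes": key.sorted_genes,
            "n_ranked_drugs": 0 if ranking is None else len(ranking.table),
            "n_candidate_drugs": 0 if ranking is None else len(ranking.candidates),
        },
    }
    if outdir:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )

    return PipelineResult(
        expression=expr,
        ground_truth=truth,
        deg_table=deg_table,
        network=network,
        core=core,
        centrality_tables=tables,
        comparison_tables=comparison,
        key_genes=key,
        correlations=correlations,
        drug_table=drug_table,
        drug_ranking=ranking,
        manifest=manifest,
    )
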