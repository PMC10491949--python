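"""End-to-end orchestration: config, pipeline run, and result tables.

One run executes, for every (enriched pathway, keyword) pair:
pathway selection -> pathway metabolites -> interacting genes ->
keyword subnetwork -> over-representation test, and writes a result
table whose columns mirror the per-pathway/keyword report layout
(pathway, #HMDB ids, #genes, keyword, node counts, subnetwork genes,
overlap, p-value). The network is either built from a catalog or loaded
from a previously serialised JSON artifact; results embed the thresholds
and input digests used, because every downstream number is
threshold-sensitive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog as catalog_mod
from .catalog import CatalogDialect, GeneUniverse
from .errors import ConfigurationError
from .mapping import (
    TableMappingProvider,
    metabolites_to_genes,
    parse_metaboanalyst,
    pathway_metabolites,
    select_pathways,
)
from .network import GwasNetwork, build_network, extract_subnetwork
from .ora import ora_test

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "pathway_name",
    "n_hmdb_ids",
    "n_metabolite_genes",
    "keyword",
    "n_primary_nodes",
    "n_neighbour_nodes",
    "n_subnetwork_genes",
    "n_overlapping_genes",
    "overlapping_genes",
    "p_value",
]


@dataclass
class RunConfig:
    """Inputs, thresholds, and keywords for one pipeline run.

    Exactly one of ``catalog`` / ``network`` must be given: a catalog
    triggers a fresh network build; a network JSON reuses a prior one.
    """

    universe: Path | None = None
    catalog: Path | None = None
    network: Path | None = None
    name_map: Path | None = None
    pathway_results: Path | None = None
    mappings: Path | None = None        # directory with the three snapshot TSVs
    keywords: list[str] = field(default_factory=list)
    fdr_max: float = 0.05
    impact_min: float = 0.0
    jaccard_min: float = 0.5
    q_max: float = 0.05
    restrict_to_study: bool = True
    out_dir: Path = Path("metlink_results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("universe", "catalog", "network", "name_map", "pathway_results", "mappings", "out_dir"):
            if key in doc and doc[key] is not None:
                doc[key] = Path(doc[key])
        return cls(**doc)

    def validate(self) -> None:
        """Aggregate every problem into one error before any work starts."""
        problems: list[str] = []
        if (self.catalog is None) == (self.network is None):
            problems.append("exactly one of 'catalog' (build) or 'network' (reuse) is required")
        if self.catalog is not None and self.universe is None:
            problems.append("'universe' is required when building from a catalog")
        for name in ("catalog", "network", "universe", "name_map", "pathway_results", "mappings"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                problems.append(f"'{name}' path does not exist: {path}")
        for name in ("name_map", "pathway_results", "mappings"):
            if getattr(self, name) is None:
                problems.append(f"'{name}' is required")
        if not self.keywords:
            problems.append("at least one keyword is required")
        for name in ("fdr_max", "impact_min", "jaccard_min", "q_max"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"threshold '{name}' must lie in [0, 1], got {value}")
        if problems:
            raise ConfigurationError("invalid run config:\n  - " + "\n  - ".join(problems))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_or_build_network(config: RunConfig) -> GwasNetwork:
    if config.network is not None:
        logger.info("reusing prebuilt network %s (build stage skipped)", config.network)
        return GwasNetwork.from_json(config.network)
    universe = GeneUniverse.from_file(config.universe)
    rows, _ = catalog_mod.parse_catalog(config.catalog, CatalogDialect())
    nodes = catalog_mod.collapse_to_nodes(rows)
    nodes, _ = catalog_mod.filter_to_universe(nodes, universe)
    logger.info("building network: %d nodes over a %d-gene universe", len(nodes), len(universe))
    return build_network(nodes, universe, jaccard_min=config.jaccard_min, q_max=config.q_max)


@dataclass
class RunResult:
    """The result table plus the network and provenance block."""

    report: pd.DataFrame
    network: GwasNetwork
    provenance: dict


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Execute the full workflow and (optionally) write result files.

    Writes ``results.tsv`` and ``results.json`` into ``config.out_dir``;
    when the network was built from a catalog, also ``network.json`` for
    reuse. Succeeds (exit intent 0) even when no test is significant —
    absence of enrichment is a result, not an error.
    """
    config.validate()
    network = _load_or_build_network(config)
    provider = TableMappingProvider.from_dir(config.mappings)
    data = parse_metaboanalyst(config.name_map, config.pathway_results)
    enriched = select_pathways(data.pathways, fdr_max=config.fdr_max, impact_min=config.impact_min)
    logger.info("%d/%d pathway(s) pass fdr <= %g, impact >= %g",
                len(enriched), len(data.pathways), config.fdr_max, config.impact_min)

    rows = []
    for pathway in enriched:
        hmdb_ids = pathway_metabolites(
            pathway, data.metabolites, provider, restrict_to_study=config.restrict_to_study
        )
        gene_set = metabolites_to_genes(hmdb_ids, provider, pathway=pathway)
        for keyword in config.keywords:
            sub = extract_subnetwork(network, keyword)
            result = ora_test(gene_set.genes, sub.genes, network.universe)
            rows.append(
                {
                    "pathway_name": pathway.pathway_name,
                    "n_hmdb_ids": len(hmdb_ids),
                    "n_metabolite_genes": len(gene_set.genes),
                    "keyword": keyword,
                    "n_primary_nodes": len(sub.primary_nodes),
                    "n_neighbour_nodes": len(sub.neighbour_nodes),
                    "n_subnetwork_genes": len(sub.genes),
                    "n_overlapping_genes": result.overlap,
                    "overlapping_genes": ";".join(result.overlapping_symbols),
                    "p_value": result.p_value,
                }
            )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    provenance = {
        "thresholds": {
            "fdr_max": config.fdr_max,
            "impact_min": config.impact_min,
            "jaccard_min": config.jaccard_min,
            "q_max": config.q_max,
        },
        "restrict_to_study": config.restrict_to_study,
        "keywords": list(config.keywords),
        "universe_digest": network.universe.digest(),
        "input_digests": {
            name: _digest(Path(p))
            for name in ("catalog", "network", "universe", "name_map", "pathway_results")
            if (p := getattr(config, name)) is not None
        },
    }

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "results.json").write_text(
            json.dumps(
                {"provenance": provenance, "results": report.to_dict("records")},
                indent=1,
                default=float,
            ),
            encoding="utf-8",
        )
        if config.catalog is not None:
            network.to_json(out / "network.json")
    return RunResult(report=report, network=network, provenance=provenance)
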