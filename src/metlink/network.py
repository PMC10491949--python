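"""Study-trait similarity network over gene sets and keyword subnetworks.

Every unordered pair of study-trait nodes gets a Jaccard coefficient over
their (universe-filtered) gene sets and an upper-tail hypergeometric
p-value for the observed overlap, with the discoverable gene universe as
the finite population. Benjamini-Hochberg adjustment runs over the full
pairwise p-value vector; an edge is retained when the Jaccard coefficient
meets ``jaccard_min`` AND the adjusted p-value meets ``q_max`` (defaults
0.5 and 0.05 — deliberately conservative, since looser Jaccard thresholds
inflate the network with weakly related studies).

A trait subnetwork is anchored by a keyword: *primary* nodes carry the
keyword in their study title or reported trait (case-insensitive
substring); *first-degree neighbours* are non-primary nodes sharing a
retained edge with at least one primary node. The union gene set of both
groups is the trait-related gene set handed to the over-representation
test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneUniverse, StudyNode, filter_to_universe

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """|a∩b| / |a∪b|; 0.0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def edge_p_value(
    a: set[str] | frozenset[str],
    b: set[str] | frozenset[str],
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two gene sets.

    P[X >= |a∩b|] for X ~ Hypergeom(N=universe_size, K=|a|, n=|b|):
    the chance of drawing at least the observed overlap when |b| genes
    are sampled without replacement from a universe containing |a|
    "successes". Symmetric in a and b.
    """
    if len(a | b) > universe_size:
        raise ValueError(
            f"universe_size ({universe_size}) smaller than |a ∪ b| ({len(a | b)})"
        )
    k = len(a & b)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


@dataclass(frozen=True)
class Edge:
    """A retained similarity edge with its statistics."""

    node_a: str
    node_b: str
    jaccard: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edge endpoints must satisfy node_a < node_b")


@dataclass
class GwasNetwork:
    """Nodes, retained edges, and the universe they were filtered against."""

    nodes: list[StudyNode]
    edges: list[Edge]
    universe: GeneUniverse
    jaccard_min: float
    q_max: float

    def node_by_id(self, node_id: str) -> StudyNode:
        for node in self.nodes:
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                pubmed_id=node.pubmed_id,
                study_title=node.study_title,
                trait=node.trait,
                genes=";".join(sorted(node.genes)),
            )
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, jaccard=e.jaccard, p_value=e.p_value, q_value=e.q_value)
        return g

    def to_json(self, path: str | Path) -> None:
        """Lossless JSON serialisation (schema versioned).

        A full-catalog build takes hours; serialising it makes the network
        a one-time artifact that keyword queries reuse in seconds.
        """
        doc = {
            "schema_version": SCHEMA_VERSION,
            "jaccard_min": self.jaccard_min,
            "q_max": self.q_max,
            "universe": {
                "source_label": self.universe.source_label,
                "digest": self.universe.digest(),
                "symbols": sorted(self.universe.symbols),
            },
            "nodes": [
                {
                    "node_id": n.node_id,
                    "pubmed_id": n.pubmed_id,
                    "study_title": n.study_title,
                    "trait": n.trait,
                    "genes": sorted(n.genes),
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "jaccard": e.jaccard,
                    "p_value": e.p_value,
                    "q_value": e.q_value,
                }
                for e in self.edges
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GwasNetwork":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported network schema version: {doc.get('schema_version')}")
        universe = GeneUniverse(
            symbols=frozenset(doc["universe"]["symbols"]),
            source_label=doc["universe"].get("source_label", ""),
        )
        nodes = [
            StudyNode(
                node_id=n["node_id"],
                pubmed_id=n["pubmed_id"],
                study_title=n["study_title"],
                trait=n["trait"],
                genes=set(n["genes"]),
            )
            for n in doc["nodes"]
        ]
        edges = [Edge(**e) for e in doc["edges"]]
        return cls(
            nodes=nodes,
            edges=edges,
            universe=universe,
            jaccard_min=doc["jaccard_min"],
            q_max=doc["q_max"],
        )

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_network(
    nodes: Iterable[StudyNode],
    universe: GeneUniverse,
    jaccard_min: float = 0.5,
    q_max: float = 0.05,
) -> GwasNetwork:
    """Build the all-pairs similarity network and keep significant edges.

    Node gene sets are first intersected with the universe (idempotent if
    already filtered). Jaccard and hypergeometric p-values are computed
    for every unordered pair; BH adjustment runs across the *full*
    pairwise p-value vector — including pairs that fail ``jaccard_min`` —
    because the two thresholds are independent criteria. Edges meeting
    both thresholds are retained, ordered by (node_a, node_b).

    Fewer than two nodes yields an empty edge set, not an error.
    """
    filtered, _ = filter_to_universe(nodes, universe, drop_empty=False)
    filtered.sort(key=lambda n: n.node_id)
    n_universe = len(universe)

    pairs = list(combinations(filtered, 2))
    if not pairs:
        return GwasNetwork(
            nodes=filtered, edges=[], universe=universe, jaccard_min=jaccard_min, q_max=q_max
        )

    jac = np.array([jaccard(a.genes, b.genes) for a, b in pairs])
    pvals = np.array([edge_p_value(a.genes, b.genes, n_universe) for a, b in pairs])
    qvals = stats.false_discovery_control(pvals, method="bh")

    edges = [
        Edge(node_a=a.node_id, node_b=b.node_id, jaccard=float(j), p_value=float(p), q_value=float(q))
        for (a, b), j, p, q in zip(pairs, jac, pvals, qvals)
        if j >= jaccard_min and q <= q_max
    ]
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    logger.info(
        "network: %d nodes, %d/%d pairs retained as edges (jaccard >= %g, q <= %g)",
        len(filtered), len(edges), len(pairs), jaccard_min, q_max,
    )
    return GwasNetwork(
        nodes=filtered, edges=edges, universe=universe, jaccard_min=jaccard_min, q_max=q_max
    )


@dataclass
class TraitSubnetwork:
    """Keyword-anchored primary nodes, their first-degree neighbours, and genes."""

    keyword: str
    primary_nodes: set[str]
    neighbour_nodes: set[str]
    genes: set[str] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.primary_nodes) + len(self.neighbour_nodes)


def extract_subnetwork(
    network: GwasNetwork,
    keyword: str | Sequence[str],
) -> TraitSubnetwork:
    """Extract the keyword-anchored subnetwork with first-degree neighbours.

    ``keyword`` may be a single term or a list combined with OR. Matching
    is a case-insensitive literal substring test against study title and
    reported trait. Nodes matching the keyword are primary even when they
    also neighbour another primary node, keeping the two sets disjoint.
    Neighbour expansion is strictly first-degree: edges among neighbours
    do not recruit further nodes.
    """
    keywords = [keyword] if isinstance(keyword, str) else list(keyword)
    keywords = [k.strip() for k in keywords if k.strip()]
    if not keywords:
        raise ValueError("keyword must be non-empty")
    needles = [k.casefold() for k in keywords]

    primary = {
        n.node_id
        for n in network.nodes
        if any(k in n.study_title.casefold() or k in n.trait.casefold() for k in needles)
    }
    if not primary:
        logger.warning("keyword %r matched no study title or trait", keywords)

    neighbours: set[str] = set()
    for e in network.edges:
        if e.node_a in primary and e.node_b not in primary:
            neighbours.add(e.node_b)
        elif e.node_b in primary and e.node_a not in primary:
            neighbours.add(e.node_a)

    members = primary | neighbours
    genes: set[str] = set()
    for node in network.nodes:
        if node.node_id in members:
            genes |= node.genes
    return TraitSubnetwork(
        keyword=" OR ".join(keywords),
        primary_nodes=primary,
        neighbour_nodes=neighbours,
        genes=genes,
    )


def write_subnetwork_tsv(
    subnetwork: TraitSubnetwork, network: GwasNetwork, path: str | Path
) -> None:
    """Report TSV: node_id, role (primary|neighbour), trait, gene count."""
    rows = []
    for node in network.nodes:
        if node.node_id in subnetwork.primary_nodes:
            role = "primary"
        elif node.node_id in subnetwork.neighbour_nodes:
            role = "neighbour"
        else:
            continue
        rows.append((node.node_id, role, node.trait, len(node.genes)))
    pd.DataFrame(rows, columns=["node_id", "role", "trait", "gene_count"]).to_csv(
        path, sep="\t", index=False
    )
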