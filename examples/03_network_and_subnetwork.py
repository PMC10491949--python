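"""Build the similarity network and extract a keyword subnetwork.

Every pair of study-trait nodes gets a Jaccard coefficient and a
hypergeometric p-value over the shared gene universe; edges need
J >= 0.5 and BH-adjusted p <= 0.05. The keyword picks primary nodes,
and retained edges add their first-degree neighbours.
"""

import tempfile
from pathlib import Path

from metlink import (
    GeneUniverse,
    build_network,
    collapse_to_nodes,
    extract_subnetwork,
    filter_to_universe,
    parse_catalog,
)
from metlink.synth import FixtureSpec, write_fixtures

spec = FixtureSpec(seed=0)
with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixtures(spec, tmp)
    universe = GeneUniverse.from_file(paths["universe"])
    rows, _ = parse_catalog(paths["catalog"])
    nodes, _ = filter_to_universe(collapse_to_nodes(rows), universe)

network = build_network(nodes, universe, jaccard_min=0.5, q_max=0.05)
print(f"{len(network.nodes)} nodes, {len(network.edges)} significant edges")
best = min(network.edges, key=lambda e: e.q_value)
print(f"strongest edge: J={best.jaccard:.3f}, p={best.p_value:.3g}, q={best.q_value:.3g}")

sub = extract_subnetwork(network, spec.keyword)
print(
    f"keyword {spec.keyword!r}: {len(sub.primary_nodes)} primary + "
    f"{len(sub.neighbour_nodes)} neighbour nodes, {len(sub.genes)} genes"
)
# The planted 5-study cluster shares 10 of 12 genes per study, so all 10
# within-cluster pairs survive the thresholds while background studies,
# drawing genes from a disjoint pool, contribute no edges.
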