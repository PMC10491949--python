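"""Collapse a GWAS Catalog associations table into study-trait nodes.

Builds a small synthetic catalog, parses it, collapses the per-SNP rows
into one node per (PubMed id, study, trait) combination, and restricts
each node's genes to the discoverable (metabolite-interacting) universe.
"""

import tempfile
from pathlib import Path

from metlink import collapse_to_nodes, filter_to_universe, parse_catalog
from metlink.synth import FixtureSpec, make_catalog, make_universe

spec = FixtureSpec(seed=0)
universe = make_universe(spec)

with tempfile.TemporaryDirectory() as tmp:
    catalog = Path(tmp) / "catalog.tsv"
    catalog.write_text(make_catalog(spec))
    rows, report = parse_catalog(catalog)

nodes = collapse_to_nodes(rows)
nodes, n_dropped = filter_to_universe(nodes, universe)

print(f"{report.n_retained} association rows -> {len(nodes)} study-trait nodes")
print(f"{n_dropped} node(s) had no discoverable gene and were dropped")
for node in nodes[:3]:
    print(f"  {node.node_id}  trait={node.trait!r}  genes={len(node.genes)}")
# Each node carries the union of mapped genes over all of its catalog rows;
# node counts below the row count show how many rows each study contributed.
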