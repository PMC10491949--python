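"""GWAS Catalog association parsing and study-trait node construction.

The GWAS Catalog "All associations" download is a tab-separated table with
one row per SNP-trait association. This module collapses those rows into
*study-trait nodes*: one node per unique (PubMed id, study title, trait)
combination, annotated with the union of mapped gene symbols over its rows.
Nodes are subsequently restricted to a *discoverable gene universe* — the
set of genes annotated as metabolite-interacting — so that the GWAS side
and the metabolomics side of an analysis share a common background.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Placeholder tokens the catalog uses where no gene symbol is mapped.
DEFAULT_PLACEHOLDERS = frozenset({"NR", "INTERGENIC"})

# Split on the catalog's intergenic separator " - " (spaces required, so
# hyphenated symbols like HLA-B survive) and on multi-gene separators.
_GENE_SPLIT = re.compile(r"\s+-\s+|[,;]")


@dataclass(frozen=True)
class CatalogDialect:
    """Column names and tokenisation rules for a catalog download.

    Defaults follow the "All associations v1.0" export. ``gene_column``
    can be switched to ``REPORTED GENE(S)`` for analyses that prefer
    author-reported genes over mapped genes.
    """

    pubmed_column: str = "PUBMEDID"
    study_column: str = "STUDY"
    trait_column: str = "DISEASE/TRAIT"
    gene_column: str = "MAPPED_GENE"
    snp_column: str = "SNPS"
    placeholder_tokens: frozenset[str] = DEFAULT_PLACEHOLDERS

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (
            self.pubmed_column,
            self.study_column,
            self.trait_column,
            self.gene_column,
        )


@dataclass(frozen=True)
class CatalogRow:
    """One association row retained from the catalog."""

    pubmed_id: str
    study_title: str
    trait: str
    mapped_gene_field: str
    snp_field: str = ""


@dataclass
class ParseReport:
    """Bookkeeping for rows dropped during parsing."""

    n_data_rows: int = 0
    n_retained: int = 0
    n_dropped_no_pubmed: int = 0

    def log(self) -> None:
        logger.info(
            "catalog parse: %d data rows, %d retained, %d dropped (no PubMed id)",
            self.n_data_rows,
            self.n_retained,
            self.n_dropped_no_pubmed,
        )


@dataclass(frozen=True)
class GeneUniverse:
    """The discoverable gene set used as the common background.

    Symbols are uppercase-normalised; membership is set semantics.
    """

    symbols: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene universe must not be empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], source_label: str = "") -> "GeneUniverse":
        cleaned = frozenset(s.strip().upper() for s in symbols if s.strip())
        return cls(symbols=cleaned, source_label=source_label)

    @classmethod
    def from_file(cls, path: str | Path, source_label: str | None = None) -> "GeneUniverse":
        """Read a plain-text universe: one gene symbol per line."""
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        return cls.from_symbols(lines, source_label=source_label or str(path))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.symbols)) + "\n", encoding="utf-8")

    def digest(self) -> str:
        """SHA-256 over the sorted symbol list; identifies the universe."""
        h = hashlib.sha256()
        for s in sorted(self.symbols):
            h.update(s.encode("utf-8"))
            h.update(b"\n")
        return h.hexdigest()


@dataclass
class StudyNode:
    """A network vertex: one study-trait combination with its gene set."""

    node_id: str
    pubmed_id: str
    study_title: str
    trait: str
    genes: set[str] = field(default_factory=set)

    @staticmethod
    def make_id(pubmed_id: str, study_title: str, trait: str) -> str:
        """Deterministic node id from the identity triple."""
        key = "\x1f".join((pubmed_id, study_title, trait)).encode("utf-8")
        return hashlib.sha1(key).hexdigest()[:12]


def parse_gene_field(
    mapped_gene_field: str,
    placeholder_tokens: frozenset[str] = DEFAULT_PLACEHOLDERS,
) -> set[str]:
    """Tokenise a catalog gene field into a set of uppercase symbols.

    Splits on the intergenic separator ``" - "`` and on ``,``/``;``,
    trims whitespace, uppercases, and drops empty tokens and placeholder
    tokens such as ``NR``. Total function: any string yields a set.
    """
    if not mapped_gene_field:
        return set()
    out: set[str] = set()
    for token in _GENE_SPLIT.split(mapped_gene_field):
        symbol = token.strip().upper()
        if symbol and symbol not in placeholder_tokens:
            out.add(symbol)
    return out


def parse_catalog(
    path: str | Path,
    dialect: CatalogDialect | None = None,
) -> tuple[list[CatalogRow], ParseReport]:
    """Parse a GWAS Catalog associations TSV into retained rows.

    Rows lacking a PubMed id are dropped and counted in the report.

    Raises
    ------
    ConfigurationError
        If a required column is missing from the header.
    """
    dialect = dialect or CatalogDialect()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"catalog file {path} is missing required column(s): {', '.join(missing)}"
        )
    has_snp = dialect.snp_column in frame.columns

    report = ParseReport(n_data_rows=len(frame))
    rows: list[CatalogRow] = []
    for rec in frame.itertuples(index=False):
        rec_d = dict(zip(frame.columns, rec))
        pubmed = str(rec_d[dialect.pubmed_column]).strip()
        if not pubmed:
            report.n_dropped_no_pubmed += 1
            continue
        rows.append(
            CatalogRow(
                pubmed_id=pubmed,
                study_title=str(rec_d[dialect.study_column]).strip(),
                trait=str(rec_d[dialect.trait_column]).strip(),
                mapped_gene_field=str(rec_d[dialect.gene_column]).strip(),
                snp_field=str(rec_d[dialect.snp_column]).strip() if has_snp else "",
            )
        )
    report.n_retained = len(rows)
    report.log()
    return rows, report


def collapse_to_nodes(
    rows: Iterable[CatalogRow],
    dialect: CatalogDialect | None = None,
) -> list[StudyNode]:
    """Collapse association rows into study-trait nodes.

    Exactly one node per distinct (pubmed_id, study_title, trait) triple;
    node genes are the union of the parsed gene fields over its rows.
    Output is sorted by node id, so collapse is deterministic and
    idempotent when re-applied to rows reconstructed from nodes.
    """
    placeholders = (dialect or CatalogDialect()).placeholder_tokens
    by_triple: dict[tuple[str, str, str], StudyNode] = {}
    for row in rows:
        triple = (row.pubmed_id, row.study_title, row.trait)
        node = by_triple.get(triple)
        if node is None:
            node = StudyNode(
                node_id=StudyNode.make_id(*triple),
                pubmed_id=row.pubmed_id,
                study_title=row.study_title,
                trait=row.trait,
            )
            by_triple[triple] = node
        node.genes |= parse_gene_field(row.mapped_gene_field, placeholders)
    return sorted(by_triple.values(), key=lambda n: n.node_id)


def filter_to_universe(
    nodes: Iterable[StudyNode],
    universe: GeneUniverse,
    drop_empty: bool = True,
) -> tuple[list[StudyNode], int]:
    """Restrict each node's genes to the discoverable universe.

    Returns the filtered nodes and the number of nodes removed because
    their filtered gene set was empty (0 when ``drop_empty`` is off).
    Applying the filter twice equals applying it once.
    """
    out: list[StudyNode] = []
    n_dropped = 0
    for node in nodes:
        kept = node.genes & universe.symbols
        if drop_empty and not kept:
            n_dropped += 1
            continue
        out.append(
            StudyNode(
                node_id=node.node_id,
                pubmed_id=node.pubmed_id,
                study_title=node.study_title,
                trait=node.trait,
                genes=set(kept),
            )
        )
    if n_dropped:
        logger.info("universe filter dropped %d node(s) with no discoverable gene", n_dropped)
    return out, n_dropped


def write_nodes_tsv(nodes: Iterable[StudyNode], path: str | Path) -> None:
    """Write a node table: id, identity triple, semicolon-joined sorted genes."""
    frame = pd.DataFrame(
        {
            "node_id": [n.node_id for n in nodes],
            "pubmed_id": [n.pubmed_id for n in nodes],
            "study_title": [n.study_title for n in nodes],
            "trait": [n.trait for n in nodes],
            "genes": [";".join(sorted(n.genes)) for n in nodes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
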