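"""Metabolite-side mapping: enriched pathways to interacting gene symbols.

Consumes the two CSV exports of MetaboAnalyst's pathway module
(``name_map`` with compound-identifier mappings, ``pathway_results`` with
per-pathway enrichment statistics), selects enriched KEGG pathways by FDR
and impact, expands a pathway to its member metabolites (HMDB ids), and
maps metabolites to interacting human gene symbols through a pluggable
``MappingProvider``. The default provider reads flat-file snapshot tables,
so the whole chain runs offline and reproducibly; a live web provider can
implement the same three lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayRecord:
    """One row of MetaboAnalyst's pathway enrichment table.

    ``impact`` is the pathway-topology score (relative-betweenness
    centrality), valued 0-1. ``kegg_id`` falls back to the pathway name
    when the export carries no id column.
    """

    pathway_name: str
    kegg_id: str
    total: int
    hits: int
    raw_p: float
    fdr: float
    impact: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.raw_p <= 1.0:
            raise ValueError(f"raw_p out of [0,1]: {self.raw_p}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr out of [0,1]: {self.fdr}")
        if not 0.0 <= self.impact <= 1.0:
            raise ValueError(f"impact out of [0,1]: {self.impact}")
        if self.hits > self.total:
            raise ValueError(f"hits ({self.hits}) exceed total ({self.total})")


@dataclass(frozen=True)
class MetaboliteRecord:
    """One mapped compound from the name_map export."""

    query_name: str
    hmdb_id: str | None = None
    kegg_compound_id: str | None = None

    def __post_init__(self) -> None:
        if not self.hmdb_id and not self.kegg_compound_id:
            raise ValueError(f"metabolite {self.query_name!r} has no identifier")


@dataclass
class MetaboliteGeneSet:
    """A pathway's metabolites and their interacting gene symbols.

    ``provenance`` maps each gene symbol to the HMDB ids whose interacting
    proteins contributed it.
    """

    hmdb_ids: frozenset[str]
    genes: frozenset[str]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway: PathwayRecord | None = None
    n_proteins_without_gene: int = 0


class MappingProvider(Protocol):
    """The three lookups needed to go pathway -> metabolites -> genes.

    Implementations must be pure within a session and return empty
    results (never raise) for unknown identifiers.
    """

    def pathway_to_metabolites(self, kegg_pathway_id: str) -> set[str]:
        """HMDB ids of the pathway's member metabolites."""
        ...

    def metabolite_to_proteins(self, hmdb_id: str) -> set[str]:
        """UniProt accessions of proteins interacting with the metabolite."""
        ...

    def protein_to_gene(self, uniprot_acc: str) -> str | None:
        """Current human gene symbol for the protein, or None."""
        ...


class TableMappingProvider:
    """Mapping provider backed by three two-column TSV snapshot files.

    Files (header row required, one pair per line):
      - ``pathway_metabolites.tsv``: kegg_pathway_id <tab> hmdb_id
      - ``metabolite_proteins.tsv``: hmdb_id <tab> uniprot_acc
      - ``protein_genes.tsv``: uniprot_acc <tab> gene_symbol
    """

    def __init__(
        self,
        pathway_metabolites: Mapping[str, set[str]],
        metabolite_proteins: Mapping[str, set[str]],
        protein_genes: Mapping[str, str],
    ) -> None:
        self._pathway_metabolites = {k: set(v) for k, v in pathway_metabolites.items()}
        self._metabolite_proteins = {k: set(v) for k, v in metabolite_proteins.items()}
        self._protein_genes = dict(protein_genes)

    @classmethod
    def from_tsv(
        cls,
        pathway_metabolites_path: str | Path,
        metabolite_proteins_path: str | Path,
        protein_genes_path: str | Path,
    ) -> "TableMappingProvider":
        def read_pairs(path: str | Path) -> list[tuple[str, str]]:
            frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            if frame.shape[1] < 2:
                raise ConfigurationError(f"mapping table {path} needs two columns")
            return [
                (str(a).strip(), str(b).strip())
                for a, b in frame.iloc[:, :2].itertuples(index=False)
            ]

        pw: dict[str, set[str]] = {}
        for pathway, hmdb in read_pairs(pathway_metabolites_path):
            pw.setdefault(pathway, set()).add(hmdb)
        mp: dict[str, set[str]] = {}
        for hmdb, acc in read_pairs(metabolite_proteins_path):
            mp.setdefault(hmdb, set()).add(acc)
        pg: dict[str, str] = {}
        for acc, gene in read_pairs(protein_genes_path):
            if gene:
                pg[acc] = gene.upper()
        return cls(pw, mp, pg)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "TableMappingProvider":
        d = Path(directory)
        return cls.from_tsv(
            d / "pathway_metabolites.tsv",
            d / "metabolite_proteins.tsv",
            d / "protein_genes.tsv",
        )

    def pathway_to_metabolites(self, kegg_pathway_id: str) -> set[str]:
        return set(self._pathway_metabolites.get(kegg_pathway_id, set()))

    def metabolite_to_proteins(self, hmdb_id: str) -> set[str]:
        return set(self._metabolite_proteins.get(hmdb_id, set()))

    def protein_to_gene(self, uniprot_acc: str) -> str | None:
        return self._protein_genes.get(uniprot_acc)


@dataclass(frozen=True)
class MetaboAnalystColumns:
    """Header names in the two MetaboAnalyst exports (configurable)."""

    query: str = "Query"
    hmdb: str = "HMDB"
    kegg_compound: str = "KEGG"
    total: str = "Total"
    hits: str = "Hits"
    raw_p: str = "Raw p"
    fdr: str = "FDR"
    impact: str = "Impact"
    pathway_id: str = "Pathway ID"  # optional; name used as id when absent


@dataclass
class MetaboAnalystData:
    """Parsed name_map + pathway_results exports."""

    metabolites: list[MetaboliteRecord]
    pathways: list[PathwayRecord]
    n_unmapped_metabolites: int = 0

    @property
    def study_hmdb_ids(self) -> set[str]:
        return {m.hmdb_id for m in self.metabolites if m.hmdb_id}


def parse_metaboanalyst(
    name_map_path: str | Path,
    pathway_results_path: str | Path,
    columns: MetaboAnalystColumns | None = None,
) -> MetaboAnalystData:
    """Parse the two MetaboAnalyst pathway-module CSV exports.

    name_map rows with neither an HMDB id nor a KEGG compound id are
    dropped and counted. The pathway_results table must carry FDR and
    Impact columns; the pathway name is taken from the first (unnamed)
    column, as MetaboAnalyst writes it.
    """
    cols = columns or MetaboAnalystColumns()

    nm = pd.read_csv(name_map_path, dtype=str, keep_default_na=False)
    if cols.query not in nm.columns:
        raise ConfigurationError(
            f"name_map file {name_map_path} lacks column {cols.query!r}"
        )
    metabolites: list[MetaboliteRecord] = []
    n_unmapped = 0
    for rec in nm.to_dict("records"):
        hmdb = str(rec.get(cols.hmdb, "")).strip() or None
        kegg = str(rec.get(cols.kegg_compound, "")).strip() or None
        if hmdb is None and kegg is None:
            n_unmapped += 1
            continue
        metabolites.append(
            MetaboliteRecord(
                query_name=str(rec.get(cols.query, "")).strip(),
                hmdb_id=hmdb,
                kegg_compound_id=kegg,
            )
        )
    if n_unmapped:
        logger.info("name_map: dropped %d compound(s) with no identifier", n_unmapped)

    pr = pd.read_csv(pathway_results_path, dtype=str, keep_default_na=False)
    for needed in (cols.fdr, cols.impact):
        if needed not in pr.columns:
            raise ConfigurationError(
                f"pathway_results file {pathway_results_path} lacks column {needed!r}"
            )
    name_col = pr.columns[0]
    has_id = cols.pathway_id in pr.columns
    pathways: list[PathwayRecord] = []
    for rec in pr.to_dict("records"):
        name = str(rec[name_col]).strip()
        pathways.append(
            PathwayRecord(
                pathway_name=name,
                kegg_id=str(rec[cols.pathway_id]).strip() if has_id else name,
                total=int(float(rec.get(cols.total, 0) or 0)),
                hits=int(float(rec.get(cols.hits, 0) or 0)),
                raw_p=float(rec.get(cols.raw_p, 1.0) or 1.0),
                fdr=float(rec[cols.fdr]),
                impact=float(rec[cols.impact] or 0.0),
            )
        )
    return MetaboAnalystData(
        metabolites=metabolites,
        pathways=pathways,
        n_unmapped_metabolites=n_unmapped,
    )


def select_pathways(
    pathways: Iterable[PathwayRecord],
    fdr_max: float = 0.05,
    impact_min: float = 0.0,
) -> list[PathwayRecord]:
    """Keep pathways with fdr <= fdr_max and impact >= impact_min.

    Output is stably ordered by ascending FDR.
    """
    if not 0.0 <= fdr_max <= 1.0:
        raise ValueError(f"fdr_max out of [0,1]: {fdr_max}")
    if not 0.0 <= impact_min <= 1.0:
        raise ValueError(f"impact_min out of [0,1]: {impact_min}")
    kept = [p for p in pathways if p.fdr <= fdr_max and p.impact >= impact_min]
    return sorted(kept, key=lambda p: p.fdr)


def pathway_metabolites(
    pathway: PathwayRecord,
    study_metabolites: Iterable[MetaboliteRecord],
    provider: MappingProvider,
    restrict_to_study: bool = True,
) -> set[str]:
    """HMDB ids of the pathway's metabolites, optionally study-restricted.

    With ``restrict_to_study`` (default) only pathway members that were
    actually mapped in the study's name_map are returned, so downstream
    gene sets reflect the measured compounds rather than the whole
    pathway.
    """
    members = provider.pathway_to_metabolites(pathway.kegg_id)
    if not restrict_to_study:
        return members
    study_ids = {m.hmdb_id for m in study_metabolites if m.hmdb_id}
    return members & study_ids


def metabolites_to_genes(
    hmdb_ids: Iterable[str],
    provider: MappingProvider,
    pathway: PathwayRecord | None = None,
) -> MetaboliteGeneSet:
    """Map metabolites to interacting human gene symbols with provenance.

    Proteins that resolve to no current human gene symbol are dropped
    (and counted); a gene contributed by several metabolites appears once
    with all contributors recorded in the provenance map.
    """
    ids = frozenset(hmdb_ids)
    provenance: dict[str, set[str]] = {}
    n_dropped = 0
    for hmdb in sorted(ids):
        for acc in sorted(provider.metabolite_to_proteins(hmdb)):
            gene = provider.protein_to_gene(acc)
            if gene is None:
                n_dropped += 1
                continue
            provenance.setdefault(gene.upper(), set()).add(hmdb)
    if n_dropped:
        logger.info("dropped %d protein(s) with no human gene symbol", n_dropped)
    return MetaboliteGeneSet(
        hmdb_ids=ids,
        genes=frozenset(provenance),
        provenance={g: frozenset(v) for g, v in provenance.items()},
        pathway=pathway,
        n_proteins_without_gene=n_dropped,
    )


def write_gene_set_tsv(gene_set: MetaboliteGeneSet, path: str | Path) -> None:
    """Write gene_symbol + contributing HMDB ids (semicolon-joined)."""
    frame = pd.DataFrame(
        {
            "gene_symbol": sorted(gene_set.genes),
            "hmdb_ids": [
                ";".join(sorted(gene_set.provenance.get(g, frozenset())))
                for g in sorted(gene_set.genes)
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
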