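"""Deterministic synthetic fixtures for offline, end-to-end testing.

Real inputs to this workflow are a multi-gigabyte catalog download and
live database lookups. The generator emulates their statistical structure
at desk scale: a catalog-dialect TSV containing a *planted cluster* of
studies that share most of their genes (so the similarity network must
recover them as a connected component, with the anchor keyword planted in
exactly one member's trait), background studies with genes drawn from a
disjoint pool (so no spurious attachment), and MetaboAnalyst-style CSVs
plus mapping snapshot tables whose enriched pathway resolves to a gene
set sharing a chosen number of symbols with the cluster core.

The gene universe is partitioned into disjoint blocks (cluster core,
per-study private genes, metabolite-only filler, background pool), which
makes the end-to-end overlap count exact by construction: running
catalog -> network -> subnetwork -> ORA on any valid spec reports
k = ``planted_metabolite_gene_overlap``.

Every emitter is a pure function of the spec; the seed feeds one
pseudo-random stream per emitter (split from a master sequence), so
changing background composition never perturbs the planted cluster.
Synthetic symbols (G0001...) cannot collide with real gene vocabularies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import GeneUniverse

CATALOG_COLUMNS = ("PUBMEDID", "STUDY", "DISEASE/TRAIT", "SNPS", "MAPPED_GENE")

NAME_MAP_COLUMNS = ("Query", "Match", "HMDB", "PubChem", "ChEBI", "KEGG", "METLIN")
PATHWAY_RESULTS_COLUMNS = (
    "", "Total", "Expected", "Hits", "Raw p", "-log10(p)", "Holm adjust", "FDR", "Impact", "Pathway ID",
)

ENRICHED_PATHWAY_ID = "path00001"
NULL_PATHWAY_ID = "path00002"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study condition.

    Defaults describe the standard benchmark: a 300-gene universe, a
    5-study cluster sharing 80% of 12 genes per study, 20 background
    studies, and an enriched pathway whose gene set hits 9 of the
    cluster-core genes.
    """

    seed: int = 0
    universe_size: int = 300
    n_background_nodes: int = 20
    genes_per_node: int = 12
    cluster_size: int = 5
    cluster_overlap: float = 0.8
    keyword: str = "cardiovascular disease"
    planted_metabolite_gene_overlap: int = 9
    n_extra_metabolite_genes: int = 3

    def __post_init__(self) -> None:
        if self.cluster_size < 0 or self.cluster_size == 1:
            raise ValueError("cluster_size must be 0 or >= 2")
        if not 0.0 <= self.cluster_overlap <= 1.0:
            raise ValueError("cluster_overlap must lie in [0, 1]")
        if self.genes_per_node < 1:
            raise ValueError("genes_per_node must be >= 1")
        if self.planted_metabolite_gene_overlap > self.genes_per_node:
            raise ValueError("planted overlap cannot exceed genes_per_node")
        if self.cluster_size == 0 and self.planted_metabolite_gene_overlap > 0:
            raise ValueError("planted overlap requires a cluster")
        if self.cluster_size > 0 and self.planted_metabolite_gene_overlap > self.core_size:
            raise ValueError(
                f"planted overlap ({self.planted_metabolite_gene_overlap}) exceeds "
                f"the cluster core size ({self.core_size})"
            )
        if not self.keyword.strip():
            raise ValueError("keyword must be non-empty")
        reserved = self._n_cluster_genes + self.n_extra_metabolite_genes
        pool = self.universe_size - reserved
        need = 2 * self.genes_per_node if self.n_background_nodes > 0 else 0
        if pool < need:
            raise ValueError(
                f"universe_size ({self.universe_size}) too small: {reserved} genes are "
                f"reserved and the background pool needs >= {need}"
            )

    @property
    def core_size(self) -> int:
        """Number of genes every cluster study shares."""
        if self.cluster_size == 0:
            return 0
        return math.ceil(self.cluster_overlap * self.genes_per_node)

    @property
    def _n_cluster_genes(self) -> int:
        return self.core_size + self.cluster_size * (self.genes_per_node - self.core_size)


def _symbols(spec: FixtureSpec) -> list[str]:
    width = max(4, len(str(spec.universe_size)))
    return [f"G{i + 1:0{width}d}" for i in range(spec.universe_size)]


def make_universe(spec: FixtureSpec) -> GeneUniverse:
    """The full synthetic discoverable gene set, G0001..G{N}."""
    return GeneUniverse.from_symbols(_symbols(spec), source_label=f"synthetic (seed={spec.seed})")


def cluster_core_genes(spec: FixtureSpec) -> list[str]:
    """The genes shared by every planted-cluster study (universe prefix)."""
    return _symbols(spec)[: spec.core_size]


def _cluster_gene_sets(spec: FixtureSpec) -> list[list[str]]:
    syms = _symbols(spec)
    core = syms[: spec.core_size]
    n_private = spec.genes_per_node - spec.core_size
    sets = []
    for i in range(spec.cluster_size):
        start = spec.core_size + i * n_private
        sets.append(core + syms[start : start + n_private])
    return sets


def _metabolite_genes(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    """(planted core genes, metabolite-only filler genes)."""
    syms = _symbols(spec)
    planted = syms[: spec.planted_metabolite_gene_overlap]
    start = spec._n_cluster_genes
    filler = syms[start : start + spec.n_extra_metabolite_genes]
    return planted, filler


def _background_pool(spec: FixtureSpec) -> list[str]:
    return _symbols(spec)[spec._n_cluster_genes + spec.n_extra_metabolite_genes :]


def _rngs(spec: FixtureSpec) -> tuple[np.random.Generator, np.random.Generator]:
    catalog_ss, metab_ss = np.random.SeedSequence(spec.seed).spawn(2)
    return np.random.default_rng(catalog_ss), np.random.default_rng(metab_ss)


def make_catalog(spec: FixtureSpec) -> str:
    """Emit a catalog-dialect TSV (one row per study-gene association).

    The keyword lands in exactly one cluster study's trait; background
    traits are checked not to contain it.
    """
    catalog_rng, _ = _rngs(spec)
    lines = ["\t".join(CATALOG_COLUMNS)]
    snp_counter = 0

    def add_study(pubmed: str, title: str, trait: str, genes: list[str]) -> None:
        nonlocal snp_counter
        for gene in genes:
            snp_counter += 1
            lines.append("\t".join((pubmed, title, trait, f"rs9{snp_counter:06d}", gene)))

    for i, genes in enumerate(_cluster_gene_sets(spec)):
        trait = spec.keyword if i == 0 else f"planted companion trait {i + 1}"
        if i > 0 and spec.keyword.casefold() in trait.casefold():
            raise ValueError(f"keyword {spec.keyword!r} collides with companion trait template")
        add_study(
            pubmed=str(90000001 + i),
            title=f"Synthetic association study of planted cluster member {i + 1}",
            trait=trait,
            genes=genes,
        )

    pool = np.array(_background_pool(spec))
    for j in range(spec.n_background_nodes):
        trait = f"synthetic background trait {j + 1}"
        if spec.keyword.casefold() in trait.casefold():
            raise ValueError(f"keyword {spec.keyword!r} collides with background trait template")
        genes = sorted(catalog_rng.choice(pool, size=spec.genes_per_node, replace=False))
        add_study(
            pubmed=str(80000001 + j),
            title=f"Synthetic background association study {j + 1}",
            trait=trait,
            genes=list(genes),
        )
    return "\n".join(lines) + "\n"


@dataclass
class MetaboliteTables:
    """The five text tables the metabolite-side stages consume."""

    name_map_csv: str
    pathway_results_csv: str
    pathway_metabolites_tsv: str
    metabolite_proteins_tsv: str
    protein_genes_tsv: str


def make_metabolite_tables(spec: FixtureSpec) -> MetaboliteTables:
    """Emit MetaboAnalyst-style CSVs and mapping snapshot TSVs.

    One metabolite per target gene, one interacting protein per
    metabolite. The enriched pathway (FDR 0.01) contains all study
    metabolites plus one non-study member whose protein lacks a gene
    symbol; the null pathway (FDR 0.5) should never survive selection at
    the default threshold.
    """
    planted, filler = _metabolite_genes(spec)
    target_genes = planted + filler
    hmdb_ids = [f"HMDB{1000001 + i:07d}" for i in range(len(target_genes))]
    proteins = [f"SYNP{i + 1:04d}" for i in range(len(target_genes))]

    nonstudy_hmdb = "HMDB0999999"   # pathway member absent from the study
    orphan_protein = "SYNP9999"     # interacting protein with no human gene

    name_map = [",".join(NAME_MAP_COLUMNS)]
    for i, hmdb in enumerate(hmdb_ids):
        name_map.append(
            ",".join(
                (f"synthetic compound {i + 1}", f"Synthetic Compound {i + 1}",
                 hmdb, "", "", f"C{90001 + i:05d}", "")
            )
        )
    # a KEGG-only compound (retained) and an unmapped one (dropped, counted)
    name_map.append(",".join(("kegg only compound", "Kegg Only Compound", "", "", "", "C99998", "")))
    name_map.append(",".join(("unmapped compound", "", "", "", "", "", "")))
    name_map_csv = "\n".join(name_map) + "\n"

    n_members = len(hmdb_ids) + 1  # + the non-study member
    pathway_results = [",".join(PATHWAY_RESULTS_COLUMNS)]
    pathway_results.append(
        ",".join(
            ("Synthetic enriched pathway", str(n_members), "1.0", str(len(hmdb_ids)),
             "0.001", "3.0", "0.01", "0.01", "0.5", ENRICHED_PATHWAY_ID)
        )
    )
    pathway_results.append(
        ",".join(
            ("Synthetic null pathway", "10", "1.0", "1",
             "0.4", "0.39", "1.0", "0.5", "0.1", NULL_PATHWAY_ID)
        )
    )
    pathway_results_csv = "\n".join(pathway_results) + "\n"

    pm = ["kegg_pathway_id\thmdb_id"]
    pm += [f"{ENRICHED_PATHWAY_ID}\t{h}" for h in hmdb_ids]
    pm.append(f"{ENRICHED_PATHWAY_ID}\t{nonstudy_hmdb}")
    pm.append(f"{NULL_PATHWAY_ID}\t{nonstudy_hmdb}")

    mp = ["hmdb_id\tuniprot_acc"]
    mp += [f"{h}\t{p}" for h, p in zip(hmdb_ids, proteins)]
    mp.append(f"{nonstudy_hmdb}\t{orphan_protein}")

    pg = ["uniprot_acc\tgene_symbol"]
    pg += [f"{p}\t{g}" for p, g in zip(proteins, target_genes)]

    return MetaboliteTables(
        name_map_csv=name_map_csv,
        pathway_results_csv=pathway_results_csv,
        pathway_metabolites_tsv="\n".join(pm) + "\n",
        metabolite_proteins_tsv="\n".join(mp) + "\n",
        protein_genes_tsv="\n".join(pg) + "\n",
    )


def write_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write every fixture file into ``out_dir``; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = make_metabolite_tables(spec)
    files = {
        "catalog": (out / "catalog.tsv", make_catalog(spec)),
        "universe": (out / "universe.txt", "\n".join(sorted(make_universe(spec).symbols)) + "\n"),
        "name_map": (out / "name_map.csv", tables.name_map_csv),
        "pathway_results": (out / "pathway_results.csv", tables.pathway_results_csv),
        "pathway_metabolites": (out / "pathway_metabolites.tsv", tables.pathway_metabolites_tsv),
        "metabolite_proteins": (out / "metabolite_proteins.tsv", tables.metabolite_proteins_tsv),
        "protein_genes": (out / "protein_genes.tsv", tables.protein_genes_tsv),
    }
    paths: dict[str, Path] = {}
    for name, (path, text) in files.items():
        path.write_text(text, encoding="utf-8")
        paths[name] = path
    return paths
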