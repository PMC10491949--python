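from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metlink import (
    CatalogDialect,
    CatalogRow,
    ConfigurationError,
    GeneUniverse,
    collapse_to_nodes,
    filter_to_universe,
    parse_catalog,
    parse_gene_field,
)

SYMBOLS = st.text(alphabet="ABCX", min_size=1, max_size=3)


@pytest.mark.parametrize(
    ("field", "expected"),
    [
        ("APOA5 - APOC3", {"APOA5", "APOC3"}),
        ("", set()),
        ("agxt2, Clybl ", {"AGXT2", "CLYBL"}),
        ("NR", set()),
        ("intergenic", set()),
        ("HLA-B", {"HLA-B"}),  # hyphenated symbols survive; only " - " splits
        ("A; B - C, ,D", {"A", "B", "C", "D"}),
    ],
)
def test_gene_field_tokenisation(field: str, expected: set[str]) -> None:
    assert parse_gene_field(field) == expected


class TestParseCatalog:
    def test_row_count_and_drop_report(self, hand_catalog_path) -> None:
        rows, report = parse_catalog(hand_catalog_path)
        assert report.n_data_rows == 12
        assert len(rows) == 11
        assert report.n_dropped_no_pubmed == 1
        assert all(r.pubmed_id for r in rows)

    def test_small_tsv(self, tmp_path) -> None:
        path = tmp_path / "c.tsv"
        path.write_text(
            "PUBMEDID\tSTUDY\tDISEASE/TRAIT\tMAPPED_GENE\n"
            "1\ts\tt\tA\n"
            "2\ts\tt\tB\n"
        )
        rows, _ = parse_catalog(path)
        assert len(rows) == 2
        assert rows[0].snp_field == ""  # SNP column optional, annotation only

    def test_missing_column_names_the_column(self, tmp_path) -> None:
        path = tmp_path / "c.tsv"
        path.write_text("PUBMEDID\tSTUDY\tMAPPED_GENE\n1\ts\tA\n")
        with pytest.raises(ConfigurationError, match="DISEASE/TRAIT"):
            parse_catalog(path)

    def test_alternate_gene_column(self, tmp_path) -> None:
        path = tmp_path / "c.tsv"
        path.write_text(
            "PUBMEDID\tSTUDY\tDISEASE/TRAIT\tREPORTED GENE(S)\tMAPPED_GENE\n"
            "1\ts\tt\tREP1\tMAP1\n"
        )
        dialect = CatalogDialect(gene_column="REPORTED GENE(S)")
        rows, _ = parse_catalog(path, dialect)
        assert rows[0].mapped_gene_field == "REP1"


class TestCollapse:
    def test_union_within_triple(self) -> None:
        rows = [
            CatalogRow("1", "s", "t", "A"),
            CatalogRow("1", "s", "t", "B"),
        ]
        nodes = collapse_to_nodes(rows)
        assert len(nodes) == 1
        assert nodes[0].genes == {"A", "B"}

    def test_distinct_trait_splits_nodes(self) -> None:
        rows = [
            CatalogRow("1", "s", "t1", "A"),
            CatalogRow("1", "s", "t2", "A"),
        ]
        assert len(collapse_to_nodes(rows)) == 2

    def test_hand_catalog_collapses_to_five_nodes(self, hand_catalog_path) -> None:
        rows, _ = parse_catalog(hand_catalog_path)
        nodes = collapse_to_nodes(rows)
        assert len(nodes) == 5
        by_trait = {n.trait: n.genes for n in nodes}
        assert by_trait["Chronic kidney disease"] == {"APOA5", "APOC3", "AGXT2", "CLYBL"}
        assert by_trait["Fasting glucose"] == {"GCK"}

    @given(
        rows=st.lists(
            st.tuples(
                st.sampled_from(["1", "2", "3"]),
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["t1", "t2"]),
                st.lists(SYMBOLS, max_size=4),
            ),
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_collapse_preserves_gene_union_and_is_idempotent(self, rows) -> None:
        catalog_rows = [CatalogRow(p, s, t, ",".join(genes)) for p, s, t, genes in rows]
        nodes = collapse_to_nodes(catalog_rows)
        assert len(nodes) <= len(catalog_rows)
        union_rows = set().union(*(parse_gene_field(r.mapped_gene_field) for r in catalog_rows)) if catalog_rows else set()
        union_nodes = set().union(*(n.genes for n in nodes)) if nodes else set()
        assert union_rows == union_nodes
        # collapsing rows reconstructed from nodes reproduces the nodes
        rebuilt = collapse_to_nodes(
            CatalogRow(n.pubmed_id, n.study_title, n.trait, ",".join(sorted(n.genes)))
            for n in nodes
        )
        assert [(n.node_id, n.genes) for n in rebuilt] == [(n.node_id, n.genes) for n in nodes]


class TestUniverseFilter:
    UNIVERSE = GeneUniverse.from_symbols(["A", "B"])

    def _node(self, genes: set[str]):
        rows = [CatalogRow("1", "s", "t", ",".join(sorted(genes)))]
        return collapse_to_nodes(rows)

    def test_intersects_genes(self) -> None:
        filtered, dropped = filter_to_universe(self._node({"A", "B", "X"}), self.UNIVERSE)
        assert filtered[0].genes == {"A", "B"}
        assert dropped == 0

    def test_drop_empty_removes_node(self) -> None:
        filtered, dropped = filter_to_universe(self._node({"X"}), self.UNIVERSE)
        assert filtered == []
        assert dropped == 1

    def test_keep_empty_retains_node(self) -> None:
        filtered, dropped = filter_to_universe(
            self._node({"X"}), self.UNIVERSE, drop_empty=False
        )
        assert len(filtered) == 1
        assert filtered[0].genes == set()
        assert dropped == 0

    def test_filter_is_idempotent_and_never_adds(self) -> None:
        nodes = self._node({"A", "X"})
        once, _ = filter_to_universe(nodes, self.UNIVERSE)
        twice, _ = filter_to_universe(once, self.UNIVERSE)
        assert [n.genes for n in once] == [n.genes for n in twice]
        assert all(n.genes <= self.UNIVERSE.symbols for n in once)

    def test_empty_universe_rejected(self) -> None:
        with pytest.raises(ValueError):
            GeneUniverse.from_symbols([])
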