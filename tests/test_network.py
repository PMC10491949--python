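from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hypergeom_tail_enum, jaccard_enum
from metlink import (
    Edge,
    GeneUniverse,
    GwasNetwork,
    StudyNode,
    build_network,
    collapse_to_nodes,
    edge_p_value,
    extract_subnetwork,
    filter_to_universe,
    jaccard,
    parse_catalog,
)
from metlink.synth import FixtureSpec, make_catalog, make_universe

GENE_SETS = st.sets(st.sampled_from([f"g{i}" for i in range(10)]))


def _node(name: str, genes: set[str], trait: str = "trait", title: str = "study") -> StudyNode:
    return StudyNode(
        node_id=name, pubmed_id=name, study_title=title, trait=trait, genes=set(genes)
    )


class TestJaccard:
    def test_half_overlap(self) -> None:
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_identity_and_disjoint(self) -> None:
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard(set(), set()) == 0.0

    @given(a=GENE_SETS, b=GENE_SETS)
    @settings(deadline=None, max_examples=100)
    def test_matches_elementwise_oracle_and_is_symmetric(self, a, b) -> None:
        universe = {f"g{i}" for i in range(10)}
        assert jaccard(a, b) == jaccard_enum(a, b, universe)
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0
        assert (jaccard(a, b) == 1.0) == (a == b and bool(a))


class TestEdgePValue:
    def test_no_overlap_is_one(self) -> None:
        assert edge_p_value({"A"}, {"B"}, universe_size=10) == 1.0

    def test_enumerated_example(self) -> None:
        # overlap 2 between two 4-gene sets in a 10-gene universe:
        # 115 of the C(10,4)=210 draws contain >= 2 successes
        a = {"g1", "g2", "g3", "g4"}
        b = {"g3", "g4", "g5", "g6"}
        assert edge_p_value(a, b, universe_size=10) == pytest.approx(float(Fraction(115, 210)))

    def test_full_universe_is_certain(self) -> None:
        full = {f"g{i}" for i in range(6)}
        assert edge_p_value(full, full, universe_size=6) == pytest.approx(1.0)

    def test_universe_too_small_is_domain_error(self) -> None:
        with pytest.raises(ValueError, match="universe_size"):
            edge_p_value({"A", "B"}, {"C"}, universe_size=2)

    @given(
        data=st.data(),
        n_universe=st.integers(2, 12),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_enumeration_oracle_small_universes(self, data, n_universe) -> None:
        universe = [f"g{i}" for i in range(n_universe)]
        a = data.draw(st.sets(st.sampled_from(universe)))
        b = data.draw(st.sets(st.sampled_from(universe)))
        expected = hypergeom_tail_enum(n_universe, len(a), len(b), len(a & b))
        assert edge_p_value(a, b, n_universe) == pytest.approx(expected)
        assert edge_p_value(a, b, n_universe) == pytest.approx(edge_p_value(b, a, n_universe))


class TestBuildNetwork:
    UNIVERSE = GeneUniverse.from_symbols([f"G{i:03d}" for i in range(100)])

    def test_identical_nodes_form_one_edge(self) -> None:
        genes = {"G001", "G002", "G003", "G004"}
        net = build_network([_node("a", genes), _node("b", genes)], self.UNIVERSE)
        assert len(net.edges) == 1
        assert net.edges[0].jaccard == 1.0
        assert net.edges[0].q_value < 0.05

    def test_disjoint_nodes_form_no_edge(self) -> None:
        net = build_network(
            [_node("a", {"G001"}), _node("b", {"G002"}), _node("c", {"G003"})],
            self.UNIVERSE,
        )
        assert net.edges == []

    def test_single_node_is_edgeless(self) -> None:
        net = build_network([_node("a", {"G001"})], self.UNIVERSE)
        assert net.edges == []

    def test_planted_cluster_recovered_exactly(self) -> None:
        spec = FixtureSpec(seed=3)
        universe = make_universe(spec)
        rows, _ = parse_catalog(_write(make_catalog(spec)))
        nodes, _ = filter_to_universe(collapse_to_nodes(rows), universe)
        net = build_network(nodes, universe)
        cluster_ids = {n.node_id for n in nodes if n.pubmed_id.startswith("9")}
        assert len(cluster_ids) == spec.cluster_size
        # brute-force expectation: all C(5,2)=10 within-cluster pairs, nothing else
        edge_pairs = {(e.node_a, e.node_b) for e in net.edges}
        assert len(edge_pairs) == 10
        assert all(a in cluster_ids and b in cluster_ids for a, b in edge_pairs)

    def test_thresholds_are_anti_monotone(self) -> None:
        spec = FixtureSpec(seed=5, cluster_overlap=0.6, planted_metabolite_gene_overlap=7)
        universe = make_universe(spec)
        rows, _ = parse_catalog(_write(make_catalog(spec)))
        nodes, _ = filter_to_universe(collapse_to_nodes(rows), universe)
        base = build_network(nodes, universe, jaccard_min=0.3, q_max=0.1)
        for jmin, qmax in [(0.5, 0.1), (0.3, 0.01), (0.7, 0.001)]:
            tighter = build_network(nodes, universe, jaccard_min=jmin, q_max=qmax)
            assert {(e.node_a, e.node_b) for e in tighter.edges} <= {
                (e.node_a, e.node_b) for e in base.edges
            }

    def test_json_round_trip(self, tmp_path) -> None:
        genes = {"G001", "G002", "G003"}
        net = build_network([_node("a", genes), _node("b", genes)], self.UNIVERSE)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = GwasNetwork.from_json(path)
        assert back.edges == net.edges
        assert {n.node_id for n in back.nodes} == {n.node_id for n in net.nodes}
        assert back.universe.symbols == net.universe.symbols
        assert (back.jaccard_min, back.q_max) == (net.jaccard_min, net.q_max)


def _write(text: str):
    import tempfile

    f = tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False)
    f.write(text)
    f.close()
    return f.name


def _star_network() -> GwasNetwork:
    """1 keyword hub, 3 neighbours via retained edges, 2 isolated nodes."""
    universe = GeneUniverse.from_symbols([f"G{i}" for i in range(20)])
    hub = _node("hub", {"G0", "G1"}, trait="Chronic kidney disease")
    spokes = [_node(f"n{i}", {"G0", "G1", f"G{i + 2}"}, trait=f"spoke {i}") for i in range(3)]
    isolated = [_node(f"iso{i}", {f"G{i + 10}"}, trait=f"iso {i}") for i in range(2)]
    edges = [
        Edge(node_a=min("hub", s.node_id), node_b=max("hub", s.node_id),
             jaccard=0.67, p_value=1e-4, q_value=1e-3)
        for s in spokes
    ]
    return GwasNetwork(
        nodes=[hub, *spokes, *isolated], edges=edges, universe=universe,
        jaccard_min=0.5, q_max=0.05,
    )


class TestExtractSubnetwork:
    def test_case_insensitive_substring_match(self) -> None:
        sub = extract_subnetwork(_star_network(), "kidney")
        assert sub.primary_nodes == {"hub"}

    def test_no_match_is_empty_with_warning(self, caplog) -> None:
        with caplog.at_level("WARNING"):
            sub = extract_subnetwork(_star_network(), "nonexistent phenotype")
        assert sub.primary_nodes == set() and sub.neighbour_nodes == set()
        assert sub.genes == set()
        assert "matched no" in caplog.text

    def test_star_first_degree_neighbours_and_gene_union(self) -> None:
        sub = extract_subnetwork(_star_network(), "kidney")
        assert sub.neighbour_nodes == {"n0", "n1", "n2"}
        assert sub.genes == {"G0", "G1", "G2", "G3", "G4"}
        assert not (sub.primary_nodes & sub.neighbour_nodes)

    def test_keyword_matching_everything_has_no_neighbours(self) -> None:
        net = _star_network()
        sub = extract_subnetwork(net, ["kidney", "spoke", "iso"])  # OR-list
        assert sub.primary_nodes == {n.node_id for n in net.nodes}
        assert sub.neighbour_nodes == set()

    def test_blank_keyword_rejected(self) -> None:
        with pytest.raises(ValueError):
            extract_subnetwork(_star_network(), "  ")
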