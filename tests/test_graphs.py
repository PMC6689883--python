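"""Monomer-graph construction, serialization, reference parsing,
correctness."""

import json

import pytest

from nrpretro import chem
from nrpretro import fragmenter as F
from nrpretro import graphs as G

TRIGLYCINE = "NCC(=O)NCC(=O)NCC(=O)O"


@pytest.fixture(scope="module")
def trigly_graph():
    import nrpretro as nr

    db = nr.packaged_database()
    res = F.run(chem.parse_smiles(TRIGLYCINE), db)
    return G.build_graph(res.best), res.best, db


class TestBuildGraph:
    def test_triglycine_path_with_carboxyl_side_sources(self, trigly_graph):
        mg, best, _ = trigly_graph
        assert [n.code for n in mg.nodes] == ["Gly", "Gly", "Gly"]
        assert [(e.source, e.target, e.label) for e in mg.edges] == [
            (0, 1, "AMINO"),
            (1, 2, "AMINO"),
        ]
        # source node holds the cut's carbon atom
        for e, cut in zip(mg.edges, best.cuts):
            assert cut.carbon_atom in mg.node(e.source).atoms

    def test_edges_equal_cuts(self, trigly_graph):
        mg, best, _ = trigly_graph
        assert len(mg.edges) == len(best.cuts)

    def test_cyclic_pentaglycine_ring_degrees(self, packaged_db):
        g = chem.parse_smiles("O=C1CNC(=O)CNC(=O)CNC(=O)CNC(=O)CN1")
        mg = G.build_graph(F.run(g, packaged_db).best)
        assert len(mg.nodes) == 5 and len(mg.edges) == 5
        indeg = {n.instance_id: 0 for n in mg.nodes}
        outdeg = {n.instance_id: 0 for n in mg.nodes}
        for e in mg.edges:
            outdeg[e.source] += 1
            indeg[e.target] += 1
        assert set(indeg.values()) == {1} and set(outdeg.values()) == {1}

    def test_unmatched_molecule_single_unk_node(self):
        from nrpretro import monomers as M

        empty = M.database_from_records([])
        g = chem.parse_smiles("NC(CO)C(=O)O")
        mg = G.build_graph(F.run(g, empty).best)
        assert len(mg.nodes) == 1 and mg.nodes[0].code == G.UNKNOWN_CODE
        assert mg.edges == ()


class TestSerialize:
    def test_atomic_graph_covers_every_heavy_atom(self, trigly_graph):
        mg, best, _ = trigly_graph
        data = json.loads(G.serialize(mg, {"id": "t", "coverage": best.coverage}))
        assert len(data["atomicGraph"]) == 13
        assert data["coverage"] == 1.0

    def test_round_trip_reconstructs_graph(self, trigly_graph):
        mg, best, _ = trigly_graph
        text = G.serialize(mg, {"id": "t", "coverage": best.coverage})
        back, meta = G.deserialize(text)
        assert back == mg and meta["id"] == "t"

    def test_byte_stable(self, trigly_graph):
        mg, best, _ = trigly_graph
        meta = {"id": "t", "coverage": best.coverage}
        assert G.serialize(mg, meta) == G.serialize(mg, meta)


class TestParseReference:
    def test_path_of_three(self):
        ref = G.parse_reference("Gly,Gly,Gly@1@0,2@1")
        assert ref.codes == ("Gly", "Gly", "Gly")
        assert ref.edges == frozenset(
            {frozenset((0, 1)), frozenset((1, 2))}
        )

    def test_single_node_no_edges(self):
        ref = G.parse_reference("Ala@")
        assert ref.codes == ("Ala",) and ref.edges == frozenset()

    def test_out_of_range_neighbor_rejected(self):
        with pytest.raises(G.ReferenceParseError, match="out of range"):
            G.parse_reference("Gly,Gly@1@3")

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(G.ReferenceParseError, match="asymmetric"):
            G.parse_reference("Gly,Gly,Gly@1@0@1")

    def test_own_json_accepted(self, trigly_graph):
        mg, best, _ = trigly_graph
        ref = G.parse_reference(G.serialize(mg, {"id": "t", "coverage": 1.0}))
        assert ref.codes == ("Gly", "Gly", "Gly")
        assert len(ref.edges) == 2


class TestCorrectness:
    def test_identical_graphs_fully_correct(self, trigly_graph):
        mg, _, db = trigly_graph
        ref = G.parse_reference("Gly,Gly,Gly@1@0,2@1")
        cmp = G.correctness(mg, ref, db)
        assert cmp.correctness == 1.0 and cmp.validated

    def test_one_mislabeled_node_scores_nine_thirteenths(self, trigly_graph):
        mg, _, db = trigly_graph
        ref = G.parse_reference("Gly,Ala,Gly@1@0,2@1")
        cmp = G.correctness(mg, ref, db)
        assert cmp.correctness == pytest.approx(9 / 13)
        assert not cmp.validated

    def test_all_unknown_scores_zero(self):
        from nrpretro import monomers as M

        empty = M.database_from_records([])
        g = chem.parse_smiles(TRIGLYCINE)
        mg = G.build_graph(F.run(g, empty).best)
        ref = G.parse_reference("Gly,Gly,Gly@1@0,2@1")
        assert G.correctness(mg, ref, empty).correctness == 0.0

    def test_codes_compared_through_isomer_aliases(self, trigly_graph):
        from nrpretro import monomers as M

        mg, _, _ = trigly_graph
        db = M.database_from_records(
            [
                {"code": "Gly", "smiles": "NCC(=O)O"},
                {"code": "D-Gly-like", "smiles": "NCC(=O)O"},
            ]
        )
        ref = G.parse_reference("D-Gly-like,D-Gly-like,D-Gly-like@1@0,2@1")
        assert G.correctness(mg, ref, db).correctness == 1.0

    def test_full_correctness_implies_full_coverage(self, packaged_db):
        # every atom correctly annotated means no UNK node can exist
        g = chem.parse_smiles(TRIGLYCINE)
        best = F.run(g, packaged_db).best
        mg = G.build_graph(best)
        ref = G.parse_reference("Gly,Gly,Gly@1@0,2@1")
        if G.correctness(mg, ref, packaged_db).correctness == 1.0:
            assert best.coverage == 1.0

    def test_topology_mismatch_limits_mapping(self, trigly_graph):
        # cyclic reference vs linear prediction: only a partial, edge-
        # consistent correspondence exists
        mg, _, db = trigly_graph
        ref = G.parse_reference("Gly,Gly,Gly@1,2@0,2@0,1")
        assert G.correctness(mg, ref, db).correctness < 1.0
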