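"""The fragmentation engine: candidate mapping, exclusion filters,
combination enumeration (vs. the exhaustive oracle), splitting, annotation,
inner-bond retry, scoring, and the secondary pass."""

import pytest

import oracles
from nrpretro import bonds as B
from nrpretro import chem
from nrpretro import fragmenter as F
from nrpretro import monomers as M
from nrpretro.config import EngineConfig

TRIGLYCINE = "NCC(=O)NCC(=O)NCC(=O)O"


def candidates_for(smiles, patterns=None, config=None):
    g = chem.parse_smiles(smiles)
    patterns = patterns or B.default_primary_patterns()
    return g, F.filter_exclusions(g, F.map_candidate_bonds(g, patterns), config)


class TestMapCandidates:
    def test_triglycine_two_amide_candidates(self):
        g, cands = candidates_for(TRIGLYCINE)
        assert [c.pattern.name for c in cands] == ["AMINO", "AMINO"]

    def test_free_glycine_no_candidates(self):
        _, cands = candidates_for("NCC(=O)O")
        assert cands == []

    def test_depsipeptide_single_ester_candidate(self):
        # terminal carboxyl O-H is not an ester; only the internal C(=O)-O
        _, cands = candidates_for("NCC(=O)OC(C)C(=O)O")
        assert [c.pattern.name for c in cands] == ["ESTER"]

    def test_duplicate_bond_resolved_to_prioritized_pattern(self):
        g = chem.parse_smiles(TRIGLYCINE)
        amino = next(p for p in B.default_primary_patterns() if p.name == "AMINO")
        shadow = B.BondPattern(
            name="CC",  # any non-prioritized name reusing the same bond
            tier="primary",
            smarts="[CX3;$([CX3]=[OX1])]-[NX3]",
            cut_pairs=((0, 1),),
            carbon=0,
            prioritized=False,
            ring_exempt=False,
            repair=B.RepairRule("CC", "none", "none"),
            order=99,
        )
        cands = F.map_candidate_bonds(g, [shadow, amino])
        assert len(cands) == 2
        assert all(c.pattern.name == "AMINO" for c in cands)


class TestFilterExclusions:
    def test_acetylated_glycine_amide_retained(self):
        # CH3-C(=O) side has 3 heavy atoms: allowed
        _, cands = candidates_for("CC(=O)NCC(=O)O")
        assert len(cands) == 1

    def test_formyl_glycine_amide_excluded(self):
        # the formyl side would strand only 2 heavy atoms
        _, cands = candidates_for("O=CNCC(=O)O")
        assert cands == []

    def test_small_ring_amide_excluded(self):
        # beta-lactam-like 4-ring: ring size < 6
        _, cands = candidates_for("CC1CC(=O)N1C")
        assert cands == []

    def test_macrocyclic_amides_retained(self):
        cyclo = "O=C1CNC(=O)CNC(=O)CNC(=O)CNC(=O)CN1"
        _, cands = candidates_for(cyclo)
        assert len(cands) == 5

    def test_azole_ring_exempt_from_cycle_rule(self):
        _, cands = candidates_for("CC(N)C1=NC(C(=O)O)CS1")
        assert [c.pattern.name for c in cands] == ["HETEROCYCLE_THIAZOLE"]


class TestEnumerateCombinations:
    def test_diacetamide_two_single_cut_combinations(self):
        g, cands = candidates_for("CC(=O)NC(=O)C")
        combos = F.enumerate_combinations(g, cands)
        assert len(combos) == 2
        assert sorted(len(c.cuts) for c in combos) == [1, 1]

    def test_triglycine_one_combination_with_both_cuts(self):
        g, cands = candidates_for(TRIGLYCINE)
        combos = F.enumerate_combinations(g, cands)
        assert len(combos) == 1 and len(combos[0].cuts) == 2

    def test_no_candidates_yields_single_empty_combination(self):
        g = chem.parse_smiles("NCC(=O)O")
        combos = F.enumerate_combinations(g, [])
        assert len(combos) == 1 and combos[0].cuts == ()

    def test_combination_cap_is_an_error(self):
        g, cands = candidates_for("CC(=O)NC(=O)C")
        with pytest.raises(F.CombinatorialExplosionError):
            F.enumerate_combinations(g, cands, EngineConfig(max_combinations=1))

    def test_matches_exhaustive_oracle_on_planted_molecules(self, packaged_db):
        patterns = B.default_primary_patterns()
        for smiles in oracles.planted_molecules(packaged_db, 25, seed=11):
            g = chem.parse_smiles(smiles)
            cands = F.filter_exclusions(g, F.map_candidate_bonds(g, patterns))
            impl = {
                frozenset(c.key for c in combo.cuts)
                for combo in F.enumerate_combinations(g, cands)
            }
            assert impl == oracles.oracle_combinations(g, cands), smiles


class TestSplitMolecule:
    def test_triglycine_fragment_sizes(self):
        g, cands = candidates_for(TRIGLYCINE)
        combo = F.enumerate_combinations(g, cands)[0]
        frags = F.split_molecule(g, combo)
        assert sorted(f.size for f in frags) == [4, 4, 5]

    def test_empty_combination_single_fragment(self):
        g = chem.parse_smiles(TRIGLYCINE)
        frags = F.split_molecule(g, F.BreakCombination.of([]))
        assert len(frags) == 1 and frags[0].size == g.num_heavy_atoms

    def test_cutting_a_cycle_k_times_yields_k_fragments(self):
        cyclo = "O=C1CNC(=O)CNC(=O)CNC(=O)CNC(=O)CN1"
        g, cands = candidates_for(cyclo)
        combo = F.enumerate_combinations(g, cands)[0]
        assert len(F.split_molecule(g, combo)) == len(combo.cuts) == 5


class TestAnnotateAndScore:
    def test_triglycine_three_strict_glycines(self, aa20_db):
        g = chem.parse_smiles(TRIGLYCINE)
        res = F.run(g, aa20_db)
        assert res.best.coverage == 1.0
        assert [af.match.monomer.code for af in res.best.fragments] == ["Gly"] * 3
        assert all(af.match.mode == "STRICT" for af in res.best.fragments)

    def test_gly_sarcosine_partial_coverage_is_two_fifths(self, gly_db):
        g = chem.parse_smiles("NCC(=O)N(C)CC(=O)O")
        res = F.run(g, gly_db)
        assert F.score(res.best) == pytest.approx(0.4)

    def test_empty_database_zero_coverage(self):
        empty = M.database_from_records([])
        res = F.run(chem.parse_smiles(TRIGLYCINE), empty)
        assert res.best.coverage == 0.0

    def test_single_amino_acid_full_coverage_no_cuts(self, aa20_db):
        res = F.run(chem.parse_smiles("NC(CO)C(=O)O"), aa20_db)
        assert res.best.coverage == 1.0
        assert len(res.best.fragments) == 1 and res.best.cuts == ()

    def test_unknown_monomer_region_left_unannotated(self, aa20_db):
        # Gly-Lac-Gly: lactate absent from the 20-AA database
        g = chem.parse_smiles("NCC(=O)OC(C)C(=O)NCC(=O)O")
        res = F.run(g, aa20_db)
        assert res.best.coverage < 1.0
        assert any(af.match.mode == "NONE" for af in res.best.fragments)


class TestRetryInnerBonds:
    def test_wrongly_cut_monomer_internal_ester_merged_back(self):
        # O-acetyl-serine is a single DB monomer; the engine first cuts its
        # internal ester, leaving a 3-atom acetate that only matches after
        # un-cutting and merging
        db = M.database_from_records(
            [
                {"code": "Gly", "smiles": "NCC(=O)O"},
                {"code": "OAcSer", "smiles": "CC(=O)OCC(N)C(=O)O"},
            ]
        )
        g = chem.parse_smiles("NCC(=O)NC(COC(C)=O)C(=O)O")
        res = F.run(g, db)
        assert res.best.coverage == 1.0
        assert sorted(af.match.monomer.code for af in res.best.fragments) == [
            "Gly",
            "OAcSer",
        ]
        assert [c.pattern.name for c in res.best.cuts] == ["AMINO"]

    def test_large_fragments_not_retried(self, aa20_db):
        config = EngineConfig(max_inner_retry_atoms=8)
        # lactate fragment has 6 atoms (< 8, retried but unmatched);
        # an 9+-atom unknown is never retried: use Hiv-Gly with tiny bound
        g = chem.parse_smiles("CC(C)C(OC(=O)CN)C(=O)O")  # Gly-O-Hiv ester
        res = F.run(g, aa20_db, config=EngineConfig(max_inner_retry_atoms=2))
        assert res.best.coverage < 1.0

    def test_fragment_without_stubs_not_retried(self):
        empty = M.database_from_records([])
        g = chem.parse_smiles("NC(CO)C(=O)O")
        af = F.annotate_fragments(
            g, F.split_molecule(g, F.BreakCombination.of([])), empty
        )
        assert len(af) == 1 and not af[0].matched


class TestSecondaryPass:
    BIARYL = "NC(c1ccc(-c2ccc(C(N)C(=O)O)cc2)cc1)C(=O)O"  # two Phg, ring-ring C-C

    def test_biaryl_dimer_needs_secondary_cc_cut(self, packaged_db):
        g = chem.parse_smiles(self.BIARYL)
        primary_only = F.run(g, packaged_db, secondary=[])
        assert primary_only.best.coverage < 1.0
        res = F.run(g, packaged_db)
        assert res.best.coverage == 1.0
        assert [c.pattern.name for c in res.best.cuts] == ["CC"]
        assert sorted(af.match.monomer.code for af in res.best.fragments) == ["Phg", "Phg"]

    def test_fully_covered_primary_result_skips_secondary(self, aa20_db, monkeypatch):
        called = []
        orig = F.secondary_pass

        def spy(*args, **kwargs):
            called.append(1)
            return orig(*args, **kwargs)

        monkeypatch.setattr(F, "secondary_pass", spy)
        F.run(chem.parse_smiles(TRIGLYCINE), aa20_db)
        assert not called

    def test_unmatched_fragment_without_secondary_embeddings_unchanged(self, gly_db):
        g = chem.parse_smiles("NCC(=O)N(C)CC(=O)O")
        res = F.run(g, gly_db)
        assert res.best.coverage == pytest.approx(0.4)


class TestCycleBreakage:
    def test_six_ring_exactly_three_antipodal_pairs(self):
        g = chem.parse_smiles("C1CCNCC1")
        frag = F.Fragment(atoms=tuple(range(6)), stubs=())
        combos = F.enumerate_cycle_breakages(g, frag)
        assert len(combos) == 3
        assert all(len(c.cuts) == 2 for c in combos)
        assert all(c.cuts[0].pattern.name == "GENERIC_CYCLE" for c in combos)

    def test_five_ring_every_subset_strands_atoms(self):
        g = chem.parse_smiles("C1CNCC1")
        frag = F.Fragment(atoms=tuple(range(5)), stubs=())
        assert F.enumerate_cycle_breakages(g, frag) == []

    def test_pure_carbocycle_not_opened(self):
        g = chem.parse_smiles("C1CCCCC1")
        frag = F.Fragment(atoms=tuple(range(6)), stubs=())
        assert F.enumerate_cycle_breakages(g, frag) == []


class TestInvariants:
    def test_partition_and_no_small_fragments(self, packaged_db):
        patterns = B.default_primary_patterns()
        for smiles in oracles.planted_molecules(packaged_db, 30, seed=23):
            g = chem.parse_smiles(smiles)
            cands = F.filter_exclusions(g, F.map_candidate_bonds(g, patterns))
            for combo in F.enumerate_combinations(g, cands):
                frags = F.split_molecule(g, combo)
                atoms = [a for f in frags for a in f.atoms]
                assert sorted(atoms) == list(range(g.num_heavy_atoms))
                assert min(f.size for f in frags) >= 3

    def test_adding_unrelated_monomers_never_changes_output(self, packaged_db):
        from nrpretro import assemble as A
        from nrpretro import graphs as G

        decoys = oracles.decoy_monomers(20, seed=5)
        extended = M.MonomerDatabase(
            entries=list(packaged_db.entries)
            + M.database_from_records(decoys).entries
        )
        for spec in A.random_specs(packaged_db, 10, seed=99):
            smiles, _ = A.assemble(spec, packaged_db)
            g = chem.parse_smiles(smiles)
            base = G.serialize(G.build_graph(F.run(g, packaged_db).best), {"id": "x", "coverage": 1.0})
            ext = G.serialize(G.build_graph(F.run(g, extended).best), {"id": "x", "coverage": 1.0})
            assert base == ext

    def test_determinism_byte_identical_reruns(self, packaged_db):
        from nrpretro import graphs as G

        g1 = chem.parse_smiles(TRIGLYCINE)
        out = [
            G.serialize(
                G.build_graph(F.run(chem.parse_smiles(TRIGLYCINE), packaged_db).best),
                {"id": "t", "coverage": 1.0},
            )
            for _ in range(2)
        ]
        assert out[0] == out[1]
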