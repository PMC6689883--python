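# nrpretro

Retro-biosynthetic deconstruction of nonribosomal peptides (NRPs) into their
constituent monomers.

NRPs — microbial secondary metabolites such as vancomycin or the enniatins —
are assembled by nonribosomal peptide synthetases from building blocks that go
far beyond the 20 proteinogenic amino acids: D-amino acids, hydroxy acids,
N-methylated residues, azole heterocycles. Databases and genome-mining
pipelines describe these molecules as *monomer graphs*, but most public
structures exist only as SMILES. `nrpretro` bridges the two representations:
given a peptide SMILES and a monomer database, it reverses the biosynthetic
condensation chemistry and returns a directed monomer graph whose edges are
labeled with the bond type linking each pair of monomers.

## Method

The engine simulates retro-biosynthesis by pattern-directed bond breakage
rather than monomer tiling:

1. **Primary bond search.** SMARTS patterns locate the common inter-monomer
   linkages — amide (`AMINO`), ester (`ESTER`), thioester, and the
   thiazole/oxazole condensation motifs. Candidates on terminal branches
   (where a cut would strand ≤ 2 heavy atoms) and inside rings of fewer than
   6 atoms (azoles excepted) are excluded.
2. **Breakage combinatorics.** Adjacent candidates whose simultaneous cut
   would isolate a single atom or pair cannot be cut together; the engine
   enumerates every maximal conflict-free combination, with amide/ester cuts
   prioritized within each conflict group.
3. **Fragmentation, repair, matching.** Each combination splits the molecule
   into fragments whose termini are repaired to the free-monomer form (e.g. a
   hydroxyl is restored on the acyl side of a broken amide). Fragments are
   matched **strictly** (exact graph identity, stereochemistry ignored) and
   then **lightly** (identical skeleton, formula and bond-order multiset —
   tolerant to moved double/triple bonds, i.e. tautomers, but never to
   hydration-state changes). Small unmatched fragments are merged back into a
   neighbor when an inner monomer bond was cut by mistake.
4. **Scoring and secondary search.** Each combination is scored by *coverage*
   (annotated heavy atoms / total heavy atoms). If no combination reaches
   1.0, rarer bond types — carbon–carbon, aryl ether, and generic heterocycle
   ring-bond combinatorics — are mapped inside the still-unmatched fragments
   of the best-scoring combinations.
5. **Monomer graph.** The winning fragmentation is re-connected into a
   directed graph: edge source = the monomer holding the cut bond's carbon
   atom, target = the monomer holding the heteroatom (carboxyl side → amino
   side for a peptide bond). Given a reference annotation, a *correctness*
   value is computed: heavy atoms assigned to the expected monomer divided by
   all heavy atoms; correctness 1.0 validates the structure pair. An optional
   discovery mode reports unmatched repaired substructures as candidate new
   monomers.

The package ships a small monomer set (20 proteinogenic amino acids plus
NRP-typical monomers), file-driven bond and modification rules, and a
synthetic peptide assembler that condenses monomers into peptides with a
known ground-truth graph — the inverse operation, used to generate test
corpora.

## Worked example

```python
import nrpretro as nr

db = nr.packaged_database()
graph = nr.parse_smiles("NCC(=O)NCC(=O)NCC(=O)O")   # triglycine
result = nr.run(graph, db)
mg = nr.build_graph(result.best)

print(result.best.coverage)                  # 1.0
print([n.code for n in mg.nodes])            # ['Gly', 'Gly', 'Gly']
print([(e.source, e.target, e.label) for e in mg.edges])
# [(0, 1, 'AMINO'), (1, 2, 'AMINO')]

ref = nr.parse_reference("Gly,Ala,Gly@1@0,2@1")      # mislabeled middle node
print(nr.correctness(mg, ref, db).correctness)       # 0.6923076923076923
```

Coverage 1.0 means every one of triglycine's 13 heavy atoms sits in a matched
monomer; the two `AMINO` edges point from the carboxyl-side glycine to the
amino-side glycine. Against a reference whose middle node is wrongly `Ala`,
only the two terminal glycines (9 of 13 atoms) count as correct.

The same pipeline is available from the shell:

```bash
nrpretro generate --random 5 --seed 9 --monomers src/nrpretro/data/monomers.tsv --out gen/
nrpretro validate --input gen/peptides.tsv --monomers src/nrpretro/data/monomers.tsv \
                  --reference gen/references.tsv --out results/
# validated: 5/5
```

## Layout

- `src/nrpretro/chem.py` — molecular-graph primitives (RDKit-backed)
- `src/nrpretro/monomers.py` — monomer DB: loading, isomer grouping,
  enzymatic-modification expansion
- `src/nrpretro/bonds.py` — breakable-bond registry and terminus repair
- `src/nrpretro/fragmenter.py` — the fragmentation engine
- `src/nrpretro/matching.py` — strict/light matching
- `src/nrpretro/graphs.py` — monomer graph, serialization, correctness
- `src/nrpretro/discovery.py` — new-monomer suggestions
- `src/nrpretro/assemble.py` — synthetic peptide assembler
- `src/nrpretro/cli.py` — `nrpretro annotate | validate | generate`
- `docs/methods.md` — model, parameters, design choices, limitations
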