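# Methods

## Model

`nrpretro` treats a nonribosomal peptide as the condensation product of
free-standing monomers and inverts that chemistry. The unit of analysis is
the heavy-atom molecular graph: hydrogens are implicit throughout, and every
count the engine reports (fragment sizes, coverage, correctness) is a
heavy-atom count. Aromaticity is perceived once at parse time by RDKit's
default model, identically for peptides and monomers, so a Kekulé-written
and an aromatic-written form of the same structure can never disagree.
Stereochemistry descriptors are read but ignored by every comparison — the
method does not discriminate isomers, and monomer entries whose
stereo-stripped graphs coincide (L/D pairs) are grouped into a single entry
whose aliases retain all member codes.

Multi-component (dot-disconnected) SMILES are rejected with an explicit
error rather than silently normalized; salts and mixtures must be resolved
upstream.

## Bond chemistry

Breakable bonds live in a JSON registry (`data/bond_rules.json`) so new
types can be added without code changes. Each rule names the SMARTS
embedding atoms to cut, the carbon-side (edge-source) atom, and a repair
rule restoring the termini of the two fragments.

Primary tier (first pass): `AMINO` (amide C(=O)–N), `ESTER` (C(=O)–O with a
substituted oxygen, so free carboxyls never match), `THIOESTER`, and the
`HETEROCYCLE_THIAZOLE` / `HETEROCYCLE_OXAZOLE` condensation patterns, each
in an aromatic-azole and a 2-substituted dihydro (thiazoline/oxazoline)
variant. An azole candidate severs both ring bonds flanking the condensation
carbon (C2) in a single action: C2 travels with the upstream fragment and is
repaired to a carboxylic acid (=O and –OH added), while the downstream N and
S/O regain implicit hydrogens — reversing condensation plus
cyclodehydration. Opening a thiazoline downstream of the cut regenerates
cysteine exactly; opening an aromatic thiazole leaves a dehydro residue,
which matches when the database carries that form.

Secondary tier (mapped only inside fragments the first pass could not
identify): `CC` (aryl–aryl and exocyclic alkyl–alkyl carbon–carbon),
`ARYL_ETHER`, and the `GENERIC_CYCLE` placeholder that triggers ring-bond
combinatorics for non-azole heterocycles: all subsets (size ≥ 2) of a ring's
bonds whose joint cut strands no 1–2-atom island are tried, and the best
local annotation wins. Repair for secondary cuts adds no heavy atom; open
valences become implicit hydrogens.

Mass balance: for every amide/ester/thioester cut, the repaired fragment
formulas sum to the parent plus one water per cut. This is asserted over the
whole test corpus.

## Search

Candidates are excluded when they sit on terminal branches — operationalized
as *a cut one of whose sides holds ≤ 2 heavy atoms* — or inside rings
smaller than `min_cycle_size` (default 6; azole patterns are exempt).
Macrocycle bonds are ordinary candidates, which is how cyclic peptides open.

Adjacent candidates whose simultaneous cut would isolate a 1- or 2-atom
island conflict; the engine enumerates *all maximal conflict-free candidate
subsets*. Internally this is a maximal-independent-set enumeration over the
pairwise conflict graph (conflict-free candidates belong to every
combination), followed by a repair step for the rare higher-order islands
that only three or more joint cuts create, and by the prioritization rule:
within a conflict group containing an amide or ester candidate, selections
without one are dropped. The test suite holds this enumeration equal to an
exhaustive brute-force subset oracle on corpora of molecules with planted
imide and anhydride conflicts. Combinatorics are capped by
`max_combinations` (default 10 000); exceeding the cap is an error, never a
silent truncation.

Fragments are the connected components after bond deletion (computed on a
kekulized copy so broken aromatic rings re-sanitize cleanly). When a
repaired fragment matches nothing and has fewer than `max_inner_retry_atoms`
heavy atoms (default 8, exclusive — small fragments are the likely pieces of
a monomer), each of its cut bonds is undone in turn, non-prioritized cuts
first, and the merged fragment is re-matched; the first success replaces the
two fragments and removes that cut from the result.

Equal-coverage results tie-break deterministically: more prioritized cuts,
then fewer fragments, then the lexicographically smallest sorted list of
cut-bond atom-index pairs. Identical input, database and configuration give
byte-identical output.

## Matching

Strict matching is equality of stereo-stripped canonical SMILES — elements,
connectivity and bond orders. Light matching, consulted only after strict
fails, is equality of the triple (canonical single-bond skeleton, molecular
formula including implicit hydrogens, multiset of bond orders). It therefore
admits exactly the structures that differ in the *placement* of double or
triple bonds, and nothing else: hydrated/dehydrated pairs differ in formula
by H2 and never match, and an aromatic ring never light-matches a
non-aromatic isomer (aromatic bonds form their own multiset category — the
conservative reading that minimizes false positives). Both lookups are O(1)
against indices precomputed at database load. Among multiple hits,
database-origin entries outrank derived ones, then the lexicographically
smallest code wins.

## Monomer database and modifications

The packaged set (`data/monomers.tsv`) holds the 20 proteinogenic amino
acids and 16 NRP-typical monomers — hydroxy acids (lactate,
2-hydroxyisovalerate), diamino acids (ornithine, diaminobutyrate), dehydro
residues (Dha, Dhb), β-alanine, Aib, N-methyl variants, phenylglycines and
salicylate. It is a working set for testing and small curation tasks, not a
comprehensive catalogue; the loader accepts any TSV/JSON set.

Tailoring rules (`data/modification_rules.json`) derive candidate monomers
from existing ones: the shipped set is N-methylation of a primary α-amine
(the methyltransferase-domain reaction) and N-formylation of a primary
amine; CO is treated as a formylation, not a monomer. When several sites
match, the α-amino site is preferred — tailoring domains act on the α
position during assembly — making N-formyl-lysine come out as
6-amino-2-formamidohexanoic acid. Derived entries are flagged, outranked by
database entries during matching, and skipped when their structure collides
with an existing entry, which also makes expansion idempotent.

## Correctness

Predicted and reference graphs are aligned by an exact branch-and-bound
search for the best injective, code-compatible (through isomer-group
aliases), edge-consistent correspondence — consistency is induced-subgraph
agreement on the mapped nodes, ignoring direction and labels, since
reference graphs are undirected. Correctness is the matched nodes' heavy
atoms over all heavy atoms. The exact search runs up to 30 predicted nodes
(beyond any realistic NRP); larger graphs fall back to greedy code
matching. Edge direction for carbon–carbon and generic-cycle edges, where no
heteroatom rule applies, is fixed as smaller instance id → larger.

## Synthetic corpora

The assembler is the engine's inverse and defines the test conditions:
corpora of 200 peptides, lengths 2–10, ~25 % cyclic, amide linkages with a
25 % ester fraction, monomers drawn uniformly from the packaged codes
carrying the required functional groups, all under a fixed seed. Assembly
removes one water per linkage and emits the ground-truth reference graph.
Round-trip recovery (coverage and correctness both 1.0) is asserted for
every corpus member. The oracle-equivalence corpus plants conflicts
explicitly — random acylation of amines and hydroxyls creates imide and
anhydride motifs whose adjacent cuts would strand atoms. Decoy monomers for
the robustness check are amino-acid-like structures that each carry a
halogen, which no packaged monomer or assembled peptide contains, so they
can never match a fragment.

What these corpora do *not* emulate: monomers linked through bond types the
assembler does not form (azole, C–C — covered instead by hand-built
fixtures), erroneous or noisy input SMILES, very large structures (> ~200
heavy atoms), and the breadth of a full curated monomer database. Passing
the round-trip suite shows the engine inverts its own assembly chemistry
exactly; performance on real database curation additionally depends on the
completeness of the monomer set and bond rules supplied.

## Limitations

Polyketides and other natural-product classes following different
condensation chemistry are out of scope, as are stereochemistry-aware
matching, HELM/SCSR export, and any live database traffic in the analysis
path (the PubChem resolver exists behind the discovery interface but the
offline dictionary resolver is the default). Secondary-pass cuts are chosen
per unmatched fragment independently; a breakage spanning two unmatched
fragments at once is not considered.
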