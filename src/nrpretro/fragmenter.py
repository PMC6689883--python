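"""The retro-biosynthetic fragmentation engine.

Pipeline, per molecule: map candidate bonds with the primary SMARTS patterns,
drop those whose cut would strand one or two heavy atoms (terminal branches)
or that sit in small rings, enumerate the valid breakage combinations (the
adjacent-bond conflict combinatorics), split the molecule, repair each
fragment's termini, match fragments against the monomer database, merge small
unmatched fragments back into a neighbor when an inner monomer bond was cut by
mistake, and score each combination by the fraction of heavy atoms annotated.
If no combination reaches full coverage, a secondary pass maps the rarer bond
types (carbon–carbon, aryl ether, generic heterocycle ring combinatorics)
inside the still-unmatched fragments of the best-scoring combinations.

Everything is deterministic: candidate, combination and fragment orders are
sorted, and ties between equal-coverage results are broken by (more
prioritized cuts, fewer fragments, lexicographically smallest cut list).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property

import networkx as nx
from rdkit import Chem

from . import bonds as bondlib
from . import chem, matching
from .bonds import BondPattern
from .chem import ChemicalGraph
from .config import EngineConfig
from .monomers import MonomerDatabase

CARBON_ROLE = "carbon"
HETERO_ROLE = "hetero"


class EngineError(Exception):
    pass


class CombinatorialExplosionError(EngineError):
    """Raised when the breakage combinatorics exceed the configured cap;
    narrow the bond-pattern file or raise ``max_combinations``."""


@dataclass(frozen=True)
class CandidateBond:
    """One cut action: a pattern embedding plus the parent bond(s) it severs.

    Simple linkages sever one bond; azole patterns sever the two ring bonds
    flanking the condensation carbon in a single action.
    """

    pattern: BondPattern
    bond_pairs: tuple[tuple[int, int], ...]
    carbon_atom: int
    hetero_atom: int

    @cached_property
    def key(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(tuple(sorted(p)) for p in self.bond_pairs))

    @property
    def sort_key(self):
        return (self.key, self.pattern.name, self.pattern.order)


@dataclass(frozen=True)
class BreakCombination:
    cuts: tuple[CandidateBond, ...]

    @classmethod
    def of(cls, cuts) -> "BreakCombination":
        return cls(tuple(sorted(cuts, key=lambda c: c.sort_key)))

    @property
    def key(self):
        return tuple(c.key for c in self.cuts)


@dataclass(frozen=True)
class Stub:
    cut: CandidateBond
    role: str  # CARBON_ROLE | HETERO_ROLE


@dataclass(frozen=True)
class Fragment:
    atoms: tuple[int, ...]  # parent atom indices, sorted
    stubs: tuple[Stub, ...]

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class AnnotatedFragment:
    fragment: Fragment
    repaired: ChemicalGraph | None  # None => repair produced invalid valence
    match: matching.MatchResult

    @property
    def matched(self) -> bool:
        return self.match.matched

    @property
    def atoms(self) -> tuple[int, ...]:
        return self.fragment.atoms

    @property
    def size(self) -> int:
        return self.fragment.size


@dataclass(frozen=True)
class FragmentationResult:
    parent: ChemicalGraph
    fragments: tuple[AnnotatedFragment, ...]

    @cached_property
    def cuts(self) -> tuple[CandidateBond, ...]:
        seen = {}
        for af in self.fragments:
            for stub in af.fragment.stubs:
                seen[stub.cut.sort_key] = stub.cut
        return tuple(seen[k] for k in sorted(seen))

    @cached_property
    def coverage(self) -> float:
        total = self.parent.num_heavy_atoms
        if total == 0:
            return 0.0
        annotated = sum(af.size for af in self.fragments if af.matched)
        return annotated / total

    @property
    def unmatched(self) -> tuple[AnnotatedFragment, ...]:
        return tuple(af for af in self.fragments if not af.matched)

    @property
    def sort_key(self):
        n_prior = sum(1 for c in self.cuts if c.pattern.prioritized)
        cut_list = tuple(sorted(c.key for c in self.cuts))
        return (-self.coverage, -n_prior, len(self.fragments), cut_list)


@dataclass(frozen=True)
class RunResult:
    best: FragmentationResult
    results: tuple[FragmentationResult, ...]


def score(result: FragmentationResult) -> float:
    """Coverage: annotated heavy atoms / total heavy atoms of the parent.
    Synthetic repair atoms count in neither numerator nor denominator."""
    return result.coverage


# -- graph plumbing --------------------------------------------------------


def _adjacency(graph: ChemicalGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(graph.num_heavy_atoms)}
    for b in graph.bonds:
        adj[b.a1].add(b.a2)
        adj[b.a2].add(b.a1)
    return adj


def _components(
    graph: ChemicalGraph, cuts, restrict: set[int] | None = None
) -> list[set[int]]:
    """Connected components of (a subset of) the molecule after deleting the
    bonds of ``cuts``."""
    removed = set()
    for cut in cuts:
        for a, b in cut.bond_pairs:
            removed.add(frozenset((a, b)))
    adj = _adjacency(graph)
    nodes = set(range(graph.num_heavy_atoms)) if restrict is None else set(restrict)
    seen: set[int] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v in nodes and v not in seen and frozenset((u, v)) not in removed:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def _isolates_island(graph: ChemicalGraph, cuts, restrict=None) -> bool:
    comps = _components(graph, cuts, restrict=restrict)
    return len(comps) > 1 and min(len(c) for c in comps) <= 2


# -- candidate mapping and filtering ---------------------------------------


def map_candidate_bonds(
    graph: ChemicalGraph, patterns: list[BondPattern]
) -> list[CandidateBond]:
    """Every SMARTS embedding of every pattern, one candidate per distinct
    bond set; when two patterns claim the same bond the prioritized one wins,
    else the first-listed."""
    by_key: dict[tuple, CandidateBond] = {}
    for pattern in patterns:
        if pattern.smarts is None:
            continue
        for m in chem.match_pattern(graph, pattern.smarts, source=pattern.name):
            pairs = tuple((m[i], m[j]) for i, j in pattern.cut_pairs)
            cand = CandidateBond(
                pattern=pattern,
                bond_pairs=pairs,
                carbon_atom=m[pattern.carbon],
                hetero_atom=m[pattern.cut_pairs[0][1]],
            )
            prev = by_key.get(cand.key)
            if prev is None or (
                cand.pattern.prioritized and not prev.pattern.prioritized
            ):
                by_key[cand.key] = cand
    return sorted(by_key.values(), key=lambda c: c.sort_key)


def filter_exclusions(
    graph: ChemicalGraph,
    candidates: list[CandidateBond],
    config: EngineConfig | None = None,
) -> list[CandidateBond]:
    """Drop candidates on terminal branches (a cut stranding <= 2 heavy atoms
    on one side) and candidates inside rings smaller than ``min_cycle_size``
    unless the pattern is ring-exempt (azoles)."""
    config = config or EngineConfig()
    kept = []
    for cand in candidates:
        if not cand.pattern.ring_exempt:
            in_small_ring = False
            for a, b in cand.bond_pairs:
                bref = graph.bond_between(a, b)
                if (
                    bref is not None
                    and bref.ring_size is not None
                    and bref.ring_size < config.min_cycle_size
                ):
                    in_small_ring = True
                    break
            if in_small_ring:
                continue
        if _isolates_island(graph, [cand]):
            continue
        kept.append(cand)
    return kept


# -- combination enumeration -----------------------------------------------


def _conflict_graph(graph: ChemicalGraph, candidates: list[CandidateBond]) -> nx.Graph:
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    for i, j in itertools.combinations(range(len(candidates)), 2):
        ci, cj = candidates[i], candidates[j]
        shared = set(ci.key) & set(cj.key)
        if shared or _isolates_island(graph, [ci, cj]):
            g.add_edge(i, j)
    return g


def enumerate_combinations(
    graph: ChemicalGraph,
    candidates: list[CandidateBond],
    config: EngineConfig | None = None,
) -> list[BreakCombination]:
    """All maximal subsets of candidates whose joint cut strands no 1- or
    2-atom island, restricted by amino/ester prioritization.

    Pairwise-conflicting candidates (their joint cut isolates an island) are
    grouped by the connected components of the conflict graph; combinations
    pick a maximal independent set across them while every conflict-free
    candidate appears in every combination. Rare higher-order islands (three
    or more cuts jointly stranding an island no pair strands) are repaired by
    dropping single cuts. Within a conflict group containing a prioritized
    (amino/ester) candidate, alternatives that select no prioritized bond from
    the group are dropped.
    """
    config = config or EngineConfig()
    if not candidates:
        return [BreakCombination.of([])]
    conflict = _conflict_graph(graph, candidates)
    free = frozenset(i for i in conflict.nodes if conflict.degree(i) == 0)
    conflicted = [i for i in conflict.nodes if conflict.degree(i) > 0]
    if conflicted:
        sub = conflict.subgraph(conflicted)
        mis_list = [frozenset(cl) for cl in nx.find_cliques(nx.complement(sub))]
    else:
        mis_list = [frozenset()]
    seeds = {free | mis for mis in mis_list}

    # higher-order island repair: drop single cuts until no island remains
    valid: set[frozenset[int]] = set()
    seen: set[frozenset[int]] = set()
    stack = sorted(seeds, key=sorted)
    while stack:
        s = stack.pop()
        if s in seen:
            continue
        seen.add(s)
        if len(seen) > config.max_combinations:
            raise CombinatorialExplosionError(
                f"more than {config.max_combinations} breakage combinations; "
                "narrow the bond-pattern file or raise max_combinations"
            )
        cuts = [candidates[i] for i in s]
        if s and _isolates_island(graph, cuts):
            for i in sorted(s):
                stack.append(s - {i})
        else:
            valid.add(s)
    # keep maximal subsets only
    valid = {s for s in valid if not any(s < t for t in valid)}

    # prioritization: within each conflict component holding a prioritized
    # candidate, keep only selections that include one
    for comp in nx.connected_components(conflict.subgraph(conflicted)):
        comp = frozenset(comp)
        if not any(candidates[i].pattern.prioritized for i in comp):
            continue
        filtered = {
            s
            for s in valid
            if any(candidates[i].pattern.prioritized for i in s & comp)
        }
        if filtered:
            valid = filtered

    combos = [BreakCombination.of(candidates[i] for i in s) for s in valid]
    combos.sort(key=lambda c: c.key)
    if len(combos) > config.max_combinations:
        raise CombinatorialExplosionError(
            f"{len(combos)} combinations exceed the cap of {config.max_combinations}"
        )
    return combos


# -- splitting and annotation ----------------------------------------------


def split_molecule(graph: ChemicalGraph, combination: BreakCombination) -> list[Fragment]:
    """Connected components after deleting the combination's cut bonds, each
    with stubs recording which cuts it borders and in which role."""
    em = Chem.RWMol(graph.kekulized_mol())
    for cut in combination.cuts:
        for a, b in cut.bond_pairs:
            if em.GetBondBetweenAtoms(a, b) is not None:
                em.RemoveBond(a, b)
    pieces = Chem.GetMolFrags(em.GetMol())
    fragments = []
    for piece in pieces:
        aset = set(piece)
        stubs = []
        for cut in combination.cuts:
            if cut.carbon_atom in aset:
                stubs.append(Stub(cut, CARBON_ROLE))
            hetero_atoms = {
                atom for pair in cut.bond_pairs for atom in pair if atom != cut.carbon_atom
            }
            if hetero_atoms & aset:
                stubs.append(Stub(cut, HETERO_ROLE))
        fragments.append(Fragment(atoms=tuple(sorted(aset)), stubs=tuple(stubs)))
    fragments.sort(key=lambda f: f.atoms)
    return fragments


def _annotate_one(
    graph: ChemicalGraph, fragment: Fragment, db: MonomerDatabase
) -> AnnotatedFragment:
    repaired = bondlib.repair_fragment(graph, fragment.atoms, fragment.stubs)
    if repaired is None:
        return AnnotatedFragment(fragment, None, matching.MatchResult(None, matching.NONE))
    return AnnotatedFragment(fragment, repaired, matching.match(repaired, db))


def retry_inner_bonds(
    graph: ChemicalGraph,
    unmatched: AnnotatedFragment,
    annotated: list[AnnotatedFragment],
    db: MonomerDatabase,
    config: EngineConfig,
    undoable=None,
) -> tuple[AnnotatedFragment, list[AnnotatedFragment]] | None:
    """Try to rescue a small unmatched fragment by undoing each of its cut
    bonds in turn and re-matching the merged fragment.

    Non-prioritized cuts are undone first (a cut through a monomer-internal
    bond is more likely to be non-canonical). Returns the merged annotated
    fragment plus the fragments it replaces on first success, else None.
    """
    if unmatched.size >= config.max_inner_retry_atoms or not unmatched.fragment.stubs:
        return None
    stubs = sorted(
        unmatched.fragment.stubs,
        key=lambda s: (s.cut.pattern.prioritized, s.cut.sort_key, s.role),
    )
    tried: set[tuple] = set()
    for stub in stubs:
        cut = stub.cut
        if cut.sort_key in tried:
            continue
        tried.add(cut.sort_key)
        if undoable is not None and cut.sort_key not in undoable:
            continue
        partner = None
        for other in annotated:
            if other is unmatched:
                continue
            if any(s.cut.sort_key == cut.sort_key for s in other.fragment.stubs):
                partner = other
                break
        if partner is None:
            # both ends of the cut are inside this fragment (unsevered ring)
            merged_atoms = unmatched.atoms
            replaced = [unmatched]
            merged_stubs = [s for s in unmatched.fragment.stubs if s.cut.sort_key != cut.sort_key]
        else:
            merged_atoms = tuple(sorted(set(unmatched.atoms) | set(partner.atoms)))
            replaced = [unmatched, partner]
            merged_stubs = [
                s
                for s in unmatched.fragment.stubs + partner.fragment.stubs
                if s.cut.sort_key != cut.sort_key
            ]
        merged = Fragment(atoms=merged_atoms, stubs=tuple(merged_stubs))
        candidate = _annotate_one(graph, merged, db)
        if candidate.matched:
            return candidate, replaced
    return None


def annotate_fragments(
    graph: ChemicalGraph,
    fragments: list[Fragment],
    db: MonomerDatabase,
    config: EngineConfig | None = None,
    undoable=None,
) -> list[AnnotatedFragment]:
    """Repair and match every fragment; small unmatched fragments trigger the
    inner-bond retry, which may merge pairs of fragments."""
    config = config or EngineConfig()
    annotated = [_annotate_one(graph, f, db) for f in fragments]
    changed = True
    while changed:
        changed = False
        retryable = sorted(
            (af for af in annotated if not af.matched),
            key=lambda af: (af.size, af.atoms),
        )
        for af in retryable:
            rescue = retry_inner_bonds(graph, af, annotated, db, config, undoable=undoable)
            if rescue is not None:
                merged, replaced = rescue
                annotated = [x for x in annotated if x not in replaced]
                annotated.append(merged)
                changed = True
                break
    annotated.sort(key=lambda af: af.atoms)
    return annotated


def _annotate_combination(
    graph: ChemicalGraph,
    combination: BreakCombination,
    db: MonomerDatabase,
    config: EngineConfig,
) -> FragmentationResult:
    fragments = split_molecule(graph, combination)
    annotated = annotate_fragments(graph, fragments, db, config)
    return FragmentationResult(parent=graph, fragments=tuple(annotated))


# -- secondary pass --------------------------------------------------------


def _is_azole_ring(graph: ChemicalGraph, ring_atoms: tuple[int, ...], patterns) -> bool:
    ring = set(ring_atoms)
    for p in patterns:
        if p.smarts is None or not p.ring_exempt:
            continue
        for m in chem.match_pattern(graph, p.smarts, source=p.name):
            if set(m) == ring:
                return True
    return False


def enumerate_cycle_breakages(
    graph: ChemicalGraph,
    fragment: Fragment,
    config: EngineConfig | None = None,
    azole_patterns: list[BondPattern] | None = None,
    cycle_pattern: BondPattern | None = None,
) -> list[BreakCombination]:
    """All subsets (size >= 2) of a heterocycle's ring bonds whose joint cut
    leaves no 1–2-atom island inside the fragment, labeled GENERIC_CYCLE.

    Azole rings are excluded — they have their own condensation patterns in
    the primary tier.
    """
    config = config or EngineConfig()
    if azole_patterns is None:
        azole_patterns = bondlib.default_primary_patterns()
    if cycle_pattern is None:
        cycle_pattern = next(
            p for p in bondlib.default_secondary_patterns() if p.name == "GENERIC_CYCLE"
        )
    fragset = set(fragment.atoms)
    ring_info = graph.mol.GetRingInfo()
    combos: list[BreakCombination] = []
    seen: set[tuple] = set()
    for ring_atoms in ring_info.AtomRings():
        if not set(ring_atoms) <= fragset:
            continue
        symbols = {graph.atoms[i].element for i in ring_atoms}
        if symbols <= {"C"}:
            continue  # carbocycles are not opened by the generic rule
        if _is_azole_ring(graph, ring_atoms, azole_patterns):
            continue
        ring_bonds = []
        n = len(ring_atoms)
        for k in range(n):
            a, b = ring_atoms[k], ring_atoms[(k + 1) % n]
            ring_bonds.append((a, b))
        for size in range(2, len(ring_bonds) + 1):
            for subset in itertools.combinations(ring_bonds, size):
                cuts = [
                    CandidateBond(
                        pattern=cycle_pattern,
                        bond_pairs=((a, b),),
                        carbon_atom=a,
                        hetero_atom=b,
                    )
                    for a, b in subset
                ]
                comps = _components(graph, cuts, restrict=fragset)
                if min(len(c) for c in comps) <= 2:
                    continue
                combo = BreakCombination.of(cuts)
                if combo.key in seen:
                    continue
                seen.add(combo.key)
                combos.append(combo)
                if len(combos) > config.max_combinations:
                    raise CombinatorialExplosionError(
                        "cycle breakage combinatorics exceed max_combinations"
                    )
    combos.sort(key=lambda c: c.key)
    return combos


def _local_secondary_candidates(
    graph: ChemicalGraph,
    af: AnnotatedFragment,
    patterns: list[BondPattern],
    config: EngineConfig,
) -> list[CandidateBond]:
    fragset = set(af.fragment.atoms)
    existing = {pair for s in af.fragment.stubs for pair in s.cut.key}
    cands = []
    for cand in map_candidate_bonds(graph, patterns):
        if not all(atom in fragset for pair in cand.bond_pairs for atom in pair):
            continue
        if set(cand.key) & existing:
            continue
        # ring rule, as in the primary pass
        if not cand.pattern.ring_exempt:
            small = False
            for a, b in cand.bond_pairs:
                bref = graph.bond_between(a, b)
                if (
                    bref is not None
                    and bref.ring_size is not None
                    and bref.ring_size < config.min_cycle_size
                ):
                    small = True
            if small:
                continue
        # terminal rule, within the fragment
        if _isolates_island(graph, [cand], restrict=fragset):
            continue
        cands.append(cand)
    return cands


def _enumerate_local(
    graph: ChemicalGraph,
    fragset: set[int],
    candidates: list[CandidateBond],
    config: EngineConfig,
) -> list[frozenset[CandidateBond]]:
    """Maximal no-island subsets of local candidates, within one fragment."""
    if not candidates:
        return [frozenset()]
    conflict = nx.Graph()
    conflict.add_nodes_from(range(len(candidates)))
    for i, j in itertools.combinations(range(len(candidates)), 2):
        ci, cj = candidates[i], candidates[j]
        if set(ci.key) & set(cj.key) or _isolates_island(graph, [ci, cj], restrict=fragset):
            conflict.add_edge(i, j)
    mis_list = [frozenset(cl) for cl in nx.find_cliques(nx.complement(conflict))]
    out: set[frozenset[CandidateBond]] = set()
    for mis in mis_list:
        cuts = [candidates[i] for i in sorted(mis)]
        while cuts and _isolates_island(graph, cuts, restrict=fragset):
            cuts = cuts[:-1]  # deterministic shrink for rare higher-order islands
        out.add(frozenset(cuts))
    return sorted(out, key=lambda s: sorted(c.sort_key for c in s))


def _refine_fragment(
    graph: ChemicalGraph,
    result: FragmentationResult,
    af: AnnotatedFragment,
    secondary_patterns: list[BondPattern],
    db: MonomerDatabase,
    config: EngineConfig,
) -> list[AnnotatedFragment] | None:
    """Best secondary breakage of one unmatched fragment; None if nothing
    improves on leaving it whole."""
    fragset = set(af.fragment.atoms)
    simple = _local_secondary_candidates(graph, af, secondary_patterns, config)
    cycle_combos = enumerate_cycle_breakages(
        graph, af.fragment, config, azole_patterns=None, cycle_pattern=None
    )
    alternatives: set[frozenset[CandidateBond]] = set()
    for sc in _enumerate_local(graph, fragset, simple, config):
        alternatives.add(sc)
        for cc in cycle_combos:
            alternatives.add(sc | frozenset(cc.cuts))
    for cc in cycle_combos:
        alternatives.add(frozenset(cc.cuts))
    alternatives.discard(frozenset())
    if len(alternatives) > config.max_combinations:
        raise CombinatorialExplosionError(
            "secondary-pass combinatorics exceed max_combinations"
        )

    base_cuts = list(result.cuts)
    best = None
    for alt in sorted(alternatives, key=lambda s: sorted(c.sort_key for c in s)):
        alt_cuts = sorted(alt, key=lambda c: c.sort_key)
        comps = _components(graph, alt_cuts, restrict=fragset)
        if min(len(c) for c in comps) <= 2:
            continue
        full = BreakCombination.of(base_cuts + alt_cuts)
        pieces = [f for f in split_molecule(graph, full) if set(f.atoms) <= fragset]
        undoable = {c.sort_key for c in alt_cuts}
        annotated = annotate_fragments(graph, pieces, db, config, undoable=undoable)
        matched_atoms = sum(a.size for a in annotated if a.matched)
        key = (
            -matched_atoms,
            len(annotated),
            tuple(sorted(c.key for c in alt_cuts)),
        )
        if matched_atoms > 0 and (best is None or key < best[0]):
            best = (key, annotated)
    if best is None:
        return None
    return best[1]


def secondary_pass(
    graph: ChemicalGraph,
    results: list[FragmentationResult],
    secondary_patterns: list[BondPattern],
    db: MonomerDatabase,
    config: EngineConfig | None = None,
) -> list[FragmentationResult]:
    """Refine the unmatched fragments of the given (top-scoring) results with
    the secondary bond patterns; each fragment is processed independently."""
    config = config or EngineConfig()
    refined = []
    for result in results:
        fragments = list(result.fragments)
        for af in list(result.unmatched):
            replacement = _refine_fragment(graph, result, af, secondary_patterns, db, config)
            if replacement is not None:
                fragments = [x for x in fragments if x is not af] + replacement
        fragments.sort(key=lambda a: a.atoms)
        refined.append(FragmentationResult(parent=graph, fragments=tuple(fragments)))
    return refined


# -- full pipeline ---------------------------------------------------------


def run(
    graph: ChemicalGraph,
    db: MonomerDatabase,
    patterns: list[BondPattern] | None = None,
    secondary: list[BondPattern] | None = None,
    config: EngineConfig | None = None,
) -> RunResult:
    """Full pipeline: primary mapping → combination enumeration → fragment,
    repair, match, retry → score; secondary pass on the best tier when no
    combination reaches full coverage. Returns the best result under the
    deterministic tie-break plus all scored results."""
    config = config or EngineConfig()
    patterns = bondlib.default_primary_patterns() if patterns is None else patterns
    secondary = bondlib.default_secondary_patterns() if secondary is None else secondary

    candidates = filter_exclusions(graph, map_candidate_bonds(graph, patterns), config)
    combos = enumerate_combinations(graph, candidates, config)
    results = [_annotate_combination(graph, c, db, config) for c in combos]
    results.sort(key=lambda r: r.sort_key)

    if results and results[0].coverage < 1.0 and secondary:
        top_cov = results[0].coverage
        top = [r for r in results if r.coverage == top_cov]
        refined = secondary_pass(graph, top, secondary, db, config)
        results = sorted(refined + results, key=lambda r: r.sort_key)

    return RunResult(best=results[0], results=tuple(results))
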