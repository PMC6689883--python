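"""Monomer-graph construction, JSON serialization, reference parsing and the
correctness metric.

The monomer graph reconnects the matched fragments: one node per fragment
(unmatched fragments become ``UNK``), one directed edge per cut bond, labeled
with the bond type. The monomer holding the carbon atom of the cut is the
edge source; the monomer holding the heteroatom is the target (for a peptide
bond: carboxyl side → amino side). Carbon–carbon and generic-cycle cuts have
no heteroatom, so their direction is fixed by instance id (smaller → larger).

Correctness compares a predicted graph with a reference monomeric annotation:
the fraction of heavy atoms sitting in predicted nodes whose code agrees with
the reference node they map to, under the best code-preserving,
edge-consistent correspondence (a maximum common subgraph, exact for graphs
of realistic NRP size). A correctness of 1.0 constitutes validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .fragmenter import FragmentationResult
from .monomers import MonomerDatabase

UNKNOWN_CODE = "UNK"
_UNDIRECTED_LABELS = ("CC", "GENERIC_CYCLE")


class ReferenceParseError(Exception):
    pass


@dataclass(frozen=True)
class MGNode:
    instance_id: int
    code: str
    atoms: tuple[int, ...]
    derived: bool = False
    match_mode: str = "NONE"


@dataclass(frozen=True)
class MGEdge:
    source: int
    target: int
    label: str


@dataclass(frozen=True)
class MonomerGraph:
    nodes: tuple[MGNode, ...]
    edges: tuple[MGEdge, ...]

    @property
    def atom_map(self) -> dict[int, int]:
        return {a: n.instance_id for n in self.nodes for a in n.atoms}

    def node(self, instance_id: int) -> MGNode:
        return self.nodes[instance_id]

    def undirected_adjacency(self) -> set[frozenset[int]]:
        return {
            frozenset((e.source, e.target)) for e in self.edges if e.source != e.target
        }


@dataclass(frozen=True)
class ReferenceGraph:
    codes: tuple[str, ...]
    edges: frozenset[frozenset[int]]

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class ComparisonResult:
    correctness: float
    mapping: dict[int, int | None] = field(default_factory=dict)

    @property
    def validated(self) -> bool:
        return self.correctness == 1.0


def build_graph(best: FragmentationResult) -> MonomerGraph:
    """Reconnect the fragments of a fragmentation result into the directed,
    bond-labeled monomer graph."""
    fragments = sorted(best.fragments, key=lambda af: af.atoms)
    nodes = []
    atom_to_instance: dict[int, int] = {}
    for i, af in enumerate(fragments):
        monomer = af.match.monomer
        nodes.append(
            MGNode(
                instance_id=i,
                code=monomer.code if monomer else UNKNOWN_CODE,
                atoms=af.atoms,
                derived=bool(monomer and monomer.origin == "derived"),
                match_mode=af.match.mode,
            )
        )
        for a in af.atoms:
            atom_to_instance[a] = i
    edges = []
    for cut in best.cuts:
        label = cut.pattern.name
        carbon_node = atom_to_instance[cut.carbon_atom]
        hetero_atoms = sorted(
            {a for pair in cut.bond_pairs for a in pair if a != cut.carbon_atom}
        )
        hetero_node = atom_to_instance[hetero_atoms[0]]
        if label in _UNDIRECTED_LABELS:
            src, dst = sorted((carbon_node, hetero_node))
        else:
            src, dst = carbon_node, hetero_node
        edges.append(MGEdge(source=src, target=dst, label=label))
    edges.sort(key=lambda e: (e.source, e.target, e.label))
    return MonomerGraph(nodes=tuple(nodes), edges=tuple(edges))


# -- serialization ---------------------------------------------------------


def _round4(x: float) -> float:
    return float(f"{x:.4f}")


def serialize(graph: MonomerGraph, meta: dict) -> str:
    """Serialize a monomer graph to JSON with a fixed key order and 4-decimal
    floats, so identical graphs serialize to identical bytes.

    ``meta`` supplies ``id`` and ``coverage``, optionally ``correctness``.
    """
    payload = {
        "id": meta.get("id", ""),
        "coverage": _round4(meta["coverage"]) if "coverage" in meta else None,
        "monomericGraph": {
            "monomers": [
                {
                    "index": n.instance_id,
                    "code": n.code,
                    "derived": n.derived,
                    "matchMode": n.match_mode,
                    "atoms": list(n.atoms),
                }
                for n in graph.nodes
            ],
            "bonds": [
                {"source": e.source, "target": e.target, "label": e.label}
                for e in graph.edges
            ],
        },
        "atomicGraph": [
            {"atom": a, "monomer": m} for a, m in sorted(graph.atom_map.items())
        ],
    }
    if "correctness" in meta and meta["correctness"] is not None:
        payload["correctness"] = _round4(meta["correctness"])
    return json.dumps(payload, indent=2, sort_keys=False)


def deserialize(text: str) -> tuple[MonomerGraph, dict]:
    """Inverse of :func:`serialize`; returns the graph and the metadata."""
    data = json.loads(text)
    nodes = tuple(
        MGNode(
            instance_id=m["index"],
            code=m["code"],
            atoms=tuple(m["atoms"]),
            derived=m.get("derived", False),
            match_mode=m.get("matchMode", "NONE"),
        )
        for m in data["monomericGraph"]["monomers"]
    )
    edges = tuple(
        MGEdge(source=b["source"], target=b["target"], label=b["label"])
        for b in data["monomericGraph"]["bonds"]
    )
    meta = {k: data[k] for k in ("id", "coverage", "correctness") if k in data}
    return MonomerGraph(nodes=nodes, edges=edges), meta


# -- reference graphs ------------------------------------------------------


def parse_reference(text: str) -> ReferenceGraph:
    """Parse a reference monomeric graph.

    Accepts the compact notation ``code1,code2,…@adj-of-1@adj-of-2@…`` with
    comma-separated 0-based neighbor indices (adjacency must be symmetric),
    or this tool's own JSON output (edges read undirected).
    """
    text = text.strip()
    if not text:
        raise ReferenceParseError("empty reference graph")
    if text.startswith("{"):
        graph, _ = deserialize(text)
        return ReferenceGraph(
            codes=tuple(n.code for n in graph.nodes),
            edges=frozenset(graph.undirected_adjacency()),
        )
    parts = text.split("@")
    codes = tuple(c.strip() for c in parts[0].split(",") if c.strip())
    if not codes:
        raise ReferenceParseError("no monomer codes before the first '@'")
    adj_parts = parts[1:]
    if len(adj_parts) != len(codes):
        raise ReferenceParseError(
            f"{len(codes)} codes but {len(adj_parts)} adjacency segments"
        )
    neighbors: list[set[int]] = []
    for i, seg in enumerate(adj_parts):
        seg = seg.strip()
        ns = set()
        if seg:
            for tok in seg.split(","):
                try:
                    j = int(tok)
                except ValueError as exc:
                    raise ReferenceParseError(
                        f"segment {i}: bad neighbor index {tok!r}"
                    ) from exc
                if not (0 <= j < len(codes)):
                    raise ReferenceParseError(
                        f"segment {i}: neighbor index {j} out of range (n={len(codes)})"
                    )
                if j == i:
                    raise ReferenceParseError(f"segment {i}: self-loop")
                ns.add(j)
        neighbors.append(ns)
    for i, ns in enumerate(neighbors):
        for j in ns:
            if i not in neighbors[j]:
                raise ReferenceParseError(
                    f"asymmetric adjacency: {i}->{j} without {j}->{i}"
                )
    edges = frozenset(frozenset((i, j)) for i, ns in enumerate(neighbors) for j in ns)
    return ReferenceGraph(codes=codes, edges=edges)


# -- correctness -----------------------------------------------------------

_EXACT_SEARCH_LIMIT = 30


def _codes_compatible(pred_code: str, ref_code: str, db: MonomerDatabase | None) -> bool:
    if pred_code == UNKNOWN_CODE:
        return False
    if pred_code == ref_code:
        return True
    if db is not None:
        return db.same_group(pred_code, ref_code)
    return False


def correctness(
    predicted: MonomerGraph,
    reference: ReferenceGraph,
    db: MonomerDatabase | None = None,
) -> ComparisonResult:
    """Fraction of heavy atoms in predicted nodes whose code agrees with
    their mapped reference node, under the best edge-consistent injective
    correspondence.

    Codes are compared through isomer-group aliases when a database is
    supplied; edge direction and labels are ignored (references are
    undirected). Exact search up to 30 predicted nodes, greedy above.
    """
    total = sum(len(n.atoms) for n in predicted.nodes)
    if total == 0:
        return ComparisonResult(0.0, {})
    pred_nodes = sorted(predicted.nodes, key=lambda n: (-len(n.atoms), n.instance_id))
    pred_adj = predicted.undirected_adjacency()
    ref_adj = reference.edges

    candidates = {
        n.instance_id: [
            r for r, code in enumerate(reference.codes) if _codes_compatible(n.code, code, db)
        ]
        for n in pred_nodes
    }

    if len(pred_nodes) > _EXACT_SEARCH_LIMIT:
        mapping: dict[int, int | None] = {}
        used: set[int] = set()
        scored = 0
        for n in pred_nodes:
            pick = next((r for r in candidates[n.instance_id] if r not in used), None)
            mapping[n.instance_id] = pick
            if pick is not None:
                used.add(pick)
                scored += len(n.atoms)
        return ComparisonResult(scored / total, mapping)

    # exact branch-and-bound over node assignments
    suffix_bound = [0] * (len(pred_nodes) + 1)
    for i in range(len(pred_nodes) - 1, -1, -1):
        gain = len(pred_nodes[i].atoms) if candidates[pred_nodes[i].instance_id] else 0
        suffix_bound[i] = suffix_bound[i + 1] + gain

    best_score = 0
    best_mapping: dict[int, int | None] = {n.instance_id: None for n in pred_nodes}

    def consistent(mapping: dict[int, int], p: int, r: int) -> bool:
        for p2, r2 in mapping.items():
            if (frozenset((p, p2)) in pred_adj) != (frozenset((r, r2)) in ref_adj):
                return False
        return True

    def backtrack(i: int, mapping: dict[int, int], score: int):
        nonlocal best_score, best_mapping
        if score + suffix_bound[i] <= best_score:
            return
        if i == len(pred_nodes):
            best_score = score
            best_mapping = {n.instance_id: mapping.get(n.instance_id) for n in pred_nodes}
            return
        node = pred_nodes[i]
        for r in candidates[node.instance_id]:
            if r in mapping.values():
                continue
            if not consistent(mapping, node.instance_id, r):
                continue
            mapping[node.instance_id] = r
            backtrack(i + 1, mapping, score + len(node.atoms))
            del mapping[node.instance_id]
        backtrack(i + 1, mapping, score)  # leave this node unmapped

    backtrack(0, {}, 0)
    return ComparisonResult(best_score / total, best_mapping)
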