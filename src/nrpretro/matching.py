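"""Strict and light matching of repaired fragments against the monomer DB.

Strict matching is exact graph identity — elements, connectivity and bond
orders, stereochemistry ignored. Light matching relaxes exactly one thing:
the *placement* of double/triple bonds (same saturated skeleton, same
molecular formula including implicit hydrogens, same multiset of bond
orders). This admits tautomers and unsaturation regio-isomers while still
separating hydrated from dehydrated forms, whose formulas differ by H2.

Both run as O(1) precomputed-key lookups on the database indices.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import chem
from .chem import ChemicalGraph
from .monomers import Monomer, MonomerDatabase

STRICT = "STRICT"
LIGHT = "LIGHT"
NONE = "NONE"


@dataclass(frozen=True)
class MatchResult:
    monomer: Monomer | None
    mode: str  # STRICT | LIGHT | NONE

    @property
    def matched(self) -> bool:
        return self.monomer is not None

    def __post_init__(self):
        assert (self.monomer is None) == (self.mode == NONE)


_NO_MATCH = MatchResult(None, NONE)


def _pick(hits: list[Monomer] | None) -> Monomer | None:
    # Index hit lists are pre-sorted: database-origin entries outrank derived
    # ones, then lexicographically smallest code.
    return hits[0] if hits else None


def strict_match(fragment_graph: ChemicalGraph, db: MonomerDatabase) -> MatchResult:
    hit = _pick(db.strict_index.get(chem.strict_key(fragment_graph)))
    return MatchResult(hit, STRICT) if hit else _NO_MATCH


def light_match(fragment_graph: ChemicalGraph, db: MonomerDatabase) -> MatchResult:
    hit = _pick(db.light_index.get(chem.light_key(fragment_graph)))
    return MatchResult(hit, LIGHT) if hit else _NO_MATCH


def match(fragment_graph: ChemicalGraph, db: MonomerDatabase) -> MatchResult:
    """Strict first; light only consulted when strict fails."""
    result = strict_match(fragment_graph, db)
    if result.matched:
        return result
    return light_match(fragment_graph, db)
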