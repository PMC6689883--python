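"""Molecular graph primitives shared by the whole package.

Everything downstream manipulates :class:`ChemicalGraph`, a thin immutable
wrapper around an RDKit molecule that fixes the conventions the engine relies
on:

* hydrogens are implicit — only heavy atoms are indexed, counted and scored;
* aromaticity is perceived once, at parse time, identically for peptides and
  monomers, so aromatic/Kekulé mismatches can never break matching;
* stereochemistry descriptors are read from the SMILES but ignored by every
  comparison key (the engine does not discriminate isomers).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdMolDescriptors

# RDKit logs sanitization problems to stderr; they surface here as exceptions.
RDLogger.DisableLog("rdApp.*")

BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class ChemError(Exception):
    """Base class for chemistry-layer failures."""


class SmilesParseError(ChemError):
    """Raised when a SMILES string cannot be read.

    Carries the offending record id (if known) so batch callers can report
    which input line failed.
    """

    def __init__(self, message: str, record_id: str | None = None):
        self.record_id = record_id
        prefix = f"[record {record_id}] " if record_id is not None else ""
        super().__init__(prefix + message)


class SanitizeError(SmilesParseError):
    """Raised when a SMILES parses syntactically but fails sanitization
    (valence errors, impossible aromaticity, ...)."""


class MultiComponentError(SmilesParseError):
    """Dot-disconnected (multi-component) SMILES are rejected rather than
    silently picking a component; salts/mixtures must be normalized upstream."""


class PatternError(ChemError):
    """Invalid SMARTS in a rule file; names the source when known."""

    def __init__(self, smarts: str, source: str | None = None):
        self.smarts = smarts
        self.source = source
        where = f" (from {source})" if source else ""
        super().__init__(f"invalid SMARTS pattern {smarts!r}{where}")


@dataclass(frozen=True)
class AtomRef:
    index: int
    element: str
    formal_charge: int
    implicit_h: int
    aromatic: bool


@dataclass(frozen=True)
class BondRef:
    index: int
    a1: int
    a2: int
    order: str
    ring_size: int | None  # size of the smallest ring containing the bond

    @property
    def in_ring(self) -> bool:
        return self.ring_size is not None


class ChemicalGraph:
    """Heavy-atom molecular graph with stable atom indices.

    Atom indices are those of the underlying RDKit molecule and are stable for
    the lifetime of the object; fragments built from a parent graph keep
    referring to parent indices through explicit maps, never through this
    class.
    """

    def __init__(self, mol: Chem.Mol, source_smiles: str = ""):
        self._mol = mol
        self.source_smiles = source_smiles or Chem.MolToSmiles(mol)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str, record_id: str | None = None) -> "ChemicalGraph":
        return parse_smiles(smiles, record_id=record_id)

    # -- basic accessors --------------------------------------------------

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def num_heavy_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    @cached_property
    def atoms(self) -> tuple[AtomRef, ...]:
        return tuple(
            AtomRef(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                implicit_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
            )
            for a in self._mol.GetAtoms()
        )

    @cached_property
    def bonds(self) -> tuple[BondRef, ...]:
        refs = []
        for b in self._mol.GetBonds():
            refs.append(
                BondRef(
                    index=b.GetIdx(),
                    a1=b.GetBeginAtomIdx(),
                    a2=b.GetEndAtomIdx(),
                    order=BOND_ORDER_NAMES.get(b.GetBondType(), str(b.GetBondType()).lower()),
                    ring_size=_smallest_ring_size(self._mol, b),
                )
            )
        return tuple(refs)

    def bond_between(self, a1: int, a2: int) -> BondRef | None:
        b = self._mol.GetBondBetweenAtoms(a1, a2)
        if b is None:
            return None
        return self.bonds[b.GetIdx()]

    @cached_property
    def synthetic_atoms(self) -> frozenset[int]:
        """Indices of atoms added by fragment repair (flagged on the RDKit
        atom); empty for any graph parsed directly from SMILES."""
        out = set()
        for a in self._mol.GetAtoms():
            if a.HasProp("_synthetic"):
                out.add(a.GetIdx())
        return frozenset(out)

    # -- canonical forms ---------------------------------------------------

    def canonical_smiles(self, stereo: bool = False) -> str:
        mol = Chem.Mol(self._mol)
        if not stereo:
            Chem.RemoveStereochemistry(mol)
        return Chem.MolToSmiles(mol)

    @cached_property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self._mol)

    def kekulized_mol(self) -> Chem.Mol:
        """Fresh copy with explicit bond orders and aromatic flags cleared;
        the form used for bond deletion so that broken rings re-sanitize."""
        mol = Chem.Mol(self._mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return mol

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ChemicalGraph({self.canonical_smiles()!r}, n={self.num_heavy_atoms})"


def _smallest_ring_size(mol: Chem.Mol, bond: Chem.Bond) -> int | None:
    if not bond.IsInRing():
        return None
    for size in range(3, mol.GetNumAtoms() + 1):
        if bond.IsInRingSize(size):
            return size
    return None  # pragma: no cover - unreachable for a ring bond


def parse_smiles(smiles: str, record_id: str | None = None) -> ChemicalGraph:
    """Parse a SMILES into a sanitized :class:`ChemicalGraph`.

    Aromaticity is perceived and implicit hydrogens are computed by RDKit's
    default sanitization. Multi-component (dot-disconnected) inputs are
    rejected explicitly.
    """
    if smiles is None or not smiles.strip():
        raise SmilesParseError("empty SMILES", record_id)
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES {smiles!r}", record_id)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise MultiComponentError(
            f"multi-component SMILES {smiles!r}: normalize salts/mixtures first", record_id
        )
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise SanitizeError(f"sanitization failed for {smiles!r}: {exc}", record_id) from exc
    return ChemicalGraph(mol, source_smiles=smiles)


def match_pattern(
    graph: ChemicalGraph, pattern: str, source: str | None = None
) -> list[tuple[int, ...]]:
    """All embeddings of a SMARTS ``pattern`` in ``graph``.

    Embeddings that map the same atom set in a different order are
    deduplicated (one representative per atom set). Results are sorted for
    determinism.
    """
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise PatternError(pattern, source)
    matches = graph.mol.GetSubstructMatches(query, uniquify=True, maxMatches=100000)
    return sorted(matches)


# -- comparison keys -------------------------------------------------------


def strict_key(graph: ChemicalGraph) -> str:
    """Exact-identity key: elements, connectivity and bond orders; no stereo.

    Two graphs share a strict key iff they are the same molecule up to
    stereochemistry.
    """
    return graph.canonical_smiles(stereo=False)


def skeleton_key(graph: ChemicalGraph) -> str:
    """Canonical SMILES of the saturated carbon skeleton: same elements and
    connectivity, every bond collapsed to a single bond, hydrogens ignored."""
    skel = Chem.RWMol()
    for atom in graph.mol.GetAtoms():
        a = Chem.Atom(atom.GetAtomicNum())
        a.SetNoImplicit(True)
        skel.AddAtom(a)
    for bond in graph.mol.GetBonds():
        skel.AddBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), Chem.BondType.SINGLE)
    mol = skel.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return Chem.MolToSmiles(mol)


def bond_order_multiset(graph: ChemicalGraph) -> tuple[tuple[str, int], ...]:
    counts: dict[str, int] = {}
    for b in graph.bonds:
        counts[b.order] = counts.get(b.order, 0) + 1
    return tuple(sorted(counts.items()))


def light_key(graph: ChemicalGraph) -> tuple[str, str, tuple[tuple[str, int], ...]]:
    """Tautomer-tolerant key: (skeleton, molecular formula, bond-order
    multiset).

    Two graphs share a light key iff they differ only in the *placement* of
    their double/triple bonds: the skeleton fixes connectivity, the formula
    fixes the implicit-hydrogen count, and the multiset fixes how many bonds
    of each order exist. Hydration/dehydration pairs (formulas differing by
    H2) therefore never collide.
    """
    return (skeleton_key(graph), graph.formula, bond_order_multiset(graph))
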