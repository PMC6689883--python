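"""Registry of breakable bond types and their terminus-repair chemistry.

Primary bonds are the common inter-monomer linkages cut in the first pass
(amide, ester, thioester, and the well-characterized thiazole/oxazole
condensation patterns). Secondary bonds are rarer linkages (aryl–aryl and
alkyl–alkyl carbon–carbon, aryl ethers, generic heterocycle ring bonds) whose
mapping is restricted to the regions the first pass failed to annotate.

Each pattern names the SMARTS embedding atoms to cut (``cut_pairs``, as
indices into the mapped atoms — azole patterns cut the two ring bonds flanking
the condensation carbon in one action) and carries a repair rule restoring the
termini the free monomer has outside the molecule: cutting an amide, for
example, adds a hydroxyl to the acyl side to re-form the carboxylic acid,
while the amine side is restored by implicit-hydrogen bookkeeping alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .chem import ChemicalGraph

# The controlled edge-label vocabulary of the monomer graph.
EDGE_LABELS = (
    "AMINO",
    "ESTER",
    "THIOESTER",
    "HETEROCYCLE_THIAZOLE",
    "HETEROCYCLE_OXAZOLE",
    "CC",
    "ARYL_ETHER",
    "GENERIC_CYCLE",
)

_REPAIR_FIXES = ("none", "add_hydroxyl", "add_carboxyl")


class BondRuleError(Exception):
    """Configuration error in a bond-rule file."""


@dataclass(frozen=True)
class RepairRule:
    pattern_name: str
    carbon_side: str  # one of _REPAIR_FIXES
    hetero_side: str

    def __post_init__(self):
        for fix in (self.carbon_side, self.hetero_side):
            if fix not in _REPAIR_FIXES:
                raise BondRuleError(
                    f"unknown repair fix {fix!r} for pattern {self.pattern_name!r}"
                )


@dataclass(frozen=True)
class BondPattern:
    name: str
    tier: str  # "primary" | "secondary"
    smarts: str | None  # None => placeholder handled by cycle enumeration
    cut_pairs: tuple[tuple[int, int], ...]  # mapped-atom index pairs to cut
    carbon: int  # mapped-atom index of the carbon-side (edge source) atom
    prioritized: bool
    ring_exempt: bool
    repair: RepairRule
    order: int = 0  # position in the registry file; first-listed wins ties

    def __post_init__(self):
        if self.tier not in ("primary", "secondary"):
            raise BondRuleError(f"pattern {self.name!r}: bad tier {self.tier!r}")
        if self.name not in EDGE_LABELS:
            raise BondRuleError(
                f"pattern name {self.name!r} outside the edge-label vocabulary"
            )
        if self.smarts is not None:
            if Chem.MolFromSmarts(self.smarts) is None:
                raise BondRuleError(f"pattern {self.name!r}: invalid SMARTS {self.smarts!r}")
            if not self.cut_pairs:
                raise BondRuleError(f"pattern {self.name!r}: no cut_pairs")


def _load_rule_file(path: Path) -> list[BondPattern]:
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BondRuleError(f"{path}: not valid JSON: {exc}") from exc
    patterns = []
    for i, rec in enumerate(data):
        if "repair" not in rec:
            raise BondRuleError(
                f"{path} entry {i} ({rec.get('name', '?')}): missing repair rule"
            )
        repair = RepairRule(
            pattern_name=rec["name"],
            carbon_side=rec["repair"].get("carbon_side", "none"),
            hetero_side=rec["repair"].get("hetero_side", "none"),
        )
        patterns.append(
            BondPattern(
                name=rec["name"],
                tier=rec.get("tier", "primary"),
                smarts=rec.get("smarts"),
                cut_pairs=tuple(tuple(p) for p in rec.get("cut_pairs", [])),
                carbon=rec.get("carbon", 0),
                prioritized=bool(rec.get("prioritized", False)),
                ring_exempt=bool(rec.get("ring_exempt", False)),
                repair=repair,
                order=i,
            )
        )
    return patterns


def load_patterns(path: str | Path, tier: str | None = None) -> list[BondPattern]:
    """Load a user bond-rule file (JSON); optionally filter by tier."""
    patterns = _load_rule_file(Path(path))
    if tier is not None:
        patterns = [p for p in patterns if p.tier == tier]
    return patterns


def _packaged_patterns() -> list[BondPattern]:
    with resources.as_file(resources.files("nrpretro.data").joinpath("bond_rules.json")) as p:
        return _load_rule_file(p)


def default_primary_patterns() -> list[BondPattern]:
    """The shipped primary set: AMINO, ESTER, THIOESTER and the thiazole /
    oxazole condensation patterns (aromatic and dihydro forms)."""
    return [p for p in _packaged_patterns() if p.tier == "primary"]


def default_secondary_patterns() -> list[BondPattern]:
    """The shipped secondary set: carbon–carbon (aryl–aryl, alkyl–alkyl),
    aryl ether, and the GENERIC_CYCLE placeholder that triggers heterocycle
    ring-bond combinatorics."""
    return [p for p in _packaged_patterns() if p.tier == "secondary"]


def repair_fragment(parent, atoms, stubs):
    """Build the repaired free-standing structure of a fragment.

    ``atoms`` are parent heavy-atom indices; ``stubs`` record, for each cut
    bordering the fragment, the cut and the role this fragment held
    (``carbon`` or ``hetero``). The relevant terminus fix of each stub's
    pattern is applied; open valences left by ``none`` fixes are restored as
    implicit hydrogens during sanitization. Returns a ChemicalGraph, or None
    when the repair cannot produce a valid molecule (the fragment then stays
    unmatched).
    """
    em = Chem.RWMol(parent.kekulized_mol())
    for stub in stubs:
        for a, b in stub.cut.bond_pairs:
            if em.GetBondBetweenAtoms(a, b) is not None:
                em.RemoveBond(a, b)
    keep = sorted(set(atoms))
    keepset = set(keep)
    for idx in range(em.GetNumAtoms() - 1, -1, -1):
        if idx not in keepset:
            em.RemoveAtom(idx)
    remap = {old: new for new, old in enumerate(keep)}
    for stub in stubs:
        repair = stub.cut.pattern.repair
        if stub.role == "carbon":
            if repair.carbon_side != "none":
                apply_fix(em, remap[stub.cut.carbon_atom], repair.carbon_side)
        else:
            if repair.hetero_side != "none":
                for a, b in stub.cut.bond_pairs:
                    for atom in (a, b):
                        if atom != stub.cut.carbon_atom and atom in keepset:
                            apply_fix(em, remap[atom], repair.hetero_side)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return ChemicalGraph(mol)


def apply_fix(em: Chem.RWMol, atom_idx: int, fix: str) -> int:
    """Apply a terminus fix to ``atom_idx`` of an editable mol being repaired.

    Added heavy atoms are flagged synthetic (excluded from coverage
    bookkeeping). Returns the number of atoms added. ``none`` leaves the open
    valence to implicit-hydrogen restoration at sanitization.
    """
    if fix == "none":
        return 0
    if fix == "add_hydroxyl":
        o = Chem.Atom(8)
        o.SetProp("_synthetic", "1")
        idx = em.AddAtom(o)
        em.AddBond(atom_idx, idx, Chem.BondType.SINGLE)
        return 1
    if fix == "add_carboxyl":
        # Rebuild a carboxylic acid on a condensation carbon stripped of both
        # oxygens (azole C2 after ring opening): add =O and -OH.
        o1 = Chem.Atom(8)
        o1.SetProp("_synthetic", "1")
        o2 = Chem.Atom(8)
        o2.SetProp("_synthetic", "1")
        i1 = em.AddAtom(o1)
        em.AddBond(atom_idx, i1, Chem.BondType.DOUBLE)
        i2 = em.AddAtom(o2)
        em.AddBond(atom_idx, i2, Chem.BondType.SINGLE)
        return 2
    raise BondRuleError(f"unknown repair fix {fix!r}")
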