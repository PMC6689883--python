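"""Synthetic peptide assembler: the inverse of the fragmentation engine.

Condenses monomers from a database into a peptide SMILES left-to-right,
removing one water per AMINO/ESTER/THIOESTER linkage (donor carboxyl +
acceptor amine/hydroxyl/thiol), optionally closing last→first for cyclic
products, and returns the ground-truth reference graph alongside. This is
what test corpora are generated from: annotate(assemble(spec)) should recover
the spec's monomers and topology exactly.

Site choices are deterministic: the donor uses its first free carboxyl; the
acceptor prefers an alpha-amino site (tailoring and condensation act on the
alpha positions during NRP assembly), then the lowest atom index.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .graphs import ReferenceGraph
from .monomers import (
    ModificationRule,
    Monomer,
    MonomerDatabase,
    default_modification_rules,
)

_CARBOXYL = "[CX3](=[OX1])[OX2H1]"
_AMINE = "[NX3;H2,H1;!$([NX3][CX3]=[OX1])]"
_ALCOHOL = "[OX2H1;!$([OX2H1][CX3]=[OX1])]"
_THIOL = "[SX2H1]"
_ALPHA_AMINE = "[NX3;H2][CX4][CX3](=[OX1])[OX2]"

_ACCEPTOR_SMARTS = {"AMINO": _AMINE, "ESTER": _ALCOHOL, "THIOESTER": _THIOL}


class AssemblyError(Exception):
    pass


@dataclass(frozen=True)
class AssemblySpec:
    sequence: tuple[str, ...]
    linkages: tuple[str, ...]  # length n-1, or n if cyclic (last closes to first)
    cyclic: bool = False
    decorations: tuple[tuple[int, str], ...] = ()  # (position, modification name)

    def __post_init__(self):
        expected = len(self.sequence) if self.cyclic else len(self.sequence) - 1
        if len(self.linkages) != expected:
            raise AssemblyError(
                f"{len(self.sequence)} monomers need {expected} linkages, "
                f"got {len(self.linkages)}"
            )
        for label in self.linkages:
            if label not in _ACCEPTOR_SMARTS:
                raise AssemblyError(f"unsupported linkage label {label!r}")


def _decorated_monomer(
    monomer: Monomer, mod_name: str, rules: list[ModificationRule], position: int
) -> tuple[str, Chem.Mol]:
    rule = next((r for r in rules if r.name == mod_name), None)
    if rule is None:
        raise AssemblyError(f"position {position}: unknown modification {mod_name!r}")
    modified = rule.apply(monomer.graph)
    if modified is None:
        raise AssemblyError(
            f"position {position}: modification {mod_name!r} not applicable to "
            f"{monomer.code!r}"
        )
    return f"{rule.name}-{monomer.code}", Chem.Mol(modified.mol)


def assemble(
    spec: AssemblySpec,
    db: MonomerDatabase,
    modification_rules: list[ModificationRule] | None = None,
) -> tuple[str, ReferenceGraph]:
    """Condense ``spec.sequence`` into a single SMILES; returns it together
    with the ground-truth reference graph (codes + chain/cycle adjacency).

    Formula balance: formula(product) = sum of monomer formulas minus one
    water per linkage.
    """
    decorations = dict(spec.decorations)
    codes: list[str] = []
    mols: list[Chem.Mol] = []
    for pos, code in enumerate(spec.sequence):
        monomer = db.get(code)
        if monomer is None:
            raise AssemblyError(f"position {pos}: unknown monomer code {code!r}")
        if pos in decorations:
            rules = (
                modification_rules
                if modification_rules is not None
                else default_modification_rules()
            )
            out_code, mol = _decorated_monomer(monomer, decorations[pos], rules, pos)
        else:
            out_code, mol = monomer.code, Chem.Mol(monomer.graph.mol)
        codes.append(out_code)
        mols.append(mol)

    combined = mols[0]
    offsets = [0]
    for mol in mols[1:]:
        offsets.append(combined.GetNumAtoms())
        combined = Chem.CombineMols(combined, mol)

    def unit_matches(pos: int, smarts: str) -> list[tuple[int, ...]]:
        patt = Chem.MolFromSmarts(smarts)
        return [
            tuple(a + offsets[pos] for a in m)
            for m in mols[pos].GetSubstructMatches(patt)
        ]

    used: set[int] = set()
    new_bonds: list[tuple[int, int]] = []
    doomed_oxygens: list[int] = []

    links = [(i, i + 1, label) for i, label in enumerate(spec.linkages[: len(mols) - 1])]
    if spec.cyclic:
        links.append((len(mols) - 1, 0, spec.linkages[-1]))

    for donor, acceptor, label in links:
        carboxyls = [m for m in unit_matches(donor, _CARBOXYL) if m[0] not in used]
        if not carboxyls:
            raise AssemblyError(
                f"position {donor}: monomer {codes[donor]!r} has no free carboxyl "
                f"for a {label} linkage"
            )
        c_atom, _, oh_atom = carboxyls[0]
        sites = [m[0] for m in unit_matches(acceptor, _ACCEPTOR_SMARTS[label])]
        sites = [s for s in sites if s not in used]
        if not sites:
            raise AssemblyError(
                f"position {acceptor}: monomer {codes[acceptor]!r} has no free "
                f"{label} acceptor group"
            )
        alpha = {m[0] for m in unit_matches(acceptor, _ALPHA_AMINE)}
        site = min(sites, key=lambda s: (s not in alpha, s))
        used.update((c_atom, site))
        new_bonds.append((c_atom, site))
        doomed_oxygens.append(oh_atom)

    em = Chem.RWMol(combined)
    for a, b in new_bonds:
        em.AddBond(a, b, Chem.BondType.SINGLE)
    for idx in sorted(doomed_oxygens, reverse=True):
        em.RemoveAtom(idx)
    product = em.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # pragma: no cover - guarded by site selection
        raise AssemblyError(f"condensation produced an invalid molecule: {exc}") from exc

    edges = {frozenset((d, a)) for d, a, _ in links if d != a}
    reference = ReferenceGraph(codes=tuple(codes), edges=frozenset(edges))
    return Chem.MolToSmiles(product), reference


# -- randomized corpora ----------------------------------------------------


def _acceptor_codes(db: MonomerDatabase, label: str) -> list[str]:
    patt = Chem.MolFromSmarts(_ACCEPTOR_SMARTS[label])
    return sorted(m.code for m in db if m.graph.mol.HasSubstructMatch(patt))


def _donor_codes(db: MonomerDatabase) -> list[str]:
    patt = Chem.MolFromSmarts(_CARBOXYL)
    return sorted(m.code for m in db if m.graph.mol.HasSubstructMatch(patt))


def random_specs(
    db: MonomerDatabase,
    n: int,
    seed: int,
    min_len: int = 2,
    max_len: int = 10,
    cyclic_fraction: float = 0.25,
    ester_fraction: float = 0.25,
) -> list[AssemblySpec]:
    """Reproducible random assembly specs over the database's monomers.

    Linkages are AMINO with probability ``1 - ester_fraction`` else ESTER;
    every monomer is chosen from the codes actually carrying the functional
    groups its linkages require, so each spec assembles cleanly.
    """
    rng = random.Random(seed)
    donors = set(_donor_codes(db))
    amine_codes = [c for c in _acceptor_codes(db, "AMINO") if c in donors]
    alcohol_codes = [c for c in _acceptor_codes(db, "ESTER") if c in donors]
    if not amine_codes:
        raise AssemblyError("database has no amine-bearing monomers")
    specs = []
    for _ in range(n):
        length = rng.randint(min_len, max_len)
        cyclic = rng.random() < cyclic_fraction
        n_links = length if cyclic else length - 1
        labels = []
        for _ in range(n_links):
            use_ester = alcohol_codes and rng.random() < ester_fraction
            labels.append("ESTER" if use_ester else "AMINO")
        sequence = [rng.choice(sorted(donors))]
        for k in range(1, length):
            pool = alcohol_codes if labels[k - 1] == "ESTER" else amine_codes
            sequence.append(rng.choice(pool))
        if cyclic:
            # the closure makes monomer 0 an acceptor too
            pool = alcohol_codes if labels[-1] == "ESTER" else amine_codes
            sequence[0] = rng.choice(pool)
        specs.append(
            AssemblySpec(
                sequence=tuple(sequence), linkages=tuple(labels), cyclic=cyclic
            )
        )
    return specs
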