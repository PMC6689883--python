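"""Monomer database: loading, isomer grouping, enzymatic-modification
expansion, and the precomputed lookup keys used by strict/light matching.

A database is an immutable index over :class:`Monomer` entries. Entries whose
stereo-stripped chemical graphs are identical (stereoisomers) are grouped as a
single entry whose ``code`` is the lexicographically smallest member and whose
``aliases`` keep every member code — downstream comparisons always go through
the alias set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from rdkit import Chem

from . import chem
from .chem import ChemicalGraph

_ALPHA_AMINE_SMARTS = "[NX3;H2][CX4][CX3](=[OX1])[OX2]"


class MonomerDBError(Exception):
    """Structural problem in a monomer database file."""


@dataclass(frozen=True)
class Monomer:
    code: str
    graph: ChemicalGraph
    aliases: tuple[str, ...] = ()
    origin: str = "database"  # "database" | "derived"
    derivation: tuple[str, str] | None = None  # (parent code, modification name)

    def __post_init__(self):
        if not self.aliases:
            object.__setattr__(self, "aliases", (self.code,))

    @property
    def smiles(self) -> str:
        return self.graph.canonical_smiles()

    @property
    def strict_key(self) -> str:
        return chem.strict_key(self.graph)

    @property
    def light_key(self):
        return chem.light_key(self.graph)


@dataclass(frozen=True)
class ModificationRule:
    """A SMARTS-site + attachment-fragment rewrite modelling an enzymatic
    tailoring reaction (e.g. N-methylation by an MT domain).

    ``site_smarts``'s first mapped atom is the attachment site; the first atom
    of ``attach_smiles`` is bonded to it by a single bond. When several sites
    match, sites sitting in an alpha-amino-acid motif are preferred (tailoring
    domains act on the alpha-amino group during assembly), then the lowest
    atom index — one product per (monomer, rule).
    """

    name: str
    site_smarts: str
    attach_smiles: str

    def apply(self, graph: ChemicalGraph) -> ChemicalGraph | None:
        """Return the modified graph, or None if the rule does not apply or
        the rewrite would be chemically invalid."""
        sites = chem.match_pattern(graph, self.site_smarts, source=f"rule {self.name}")
        if not sites:
            return None
        alpha = {m[0] for m in chem.match_pattern(graph, _ALPHA_AMINE_SMARTS)}
        site = min((m[0] for m in sites), key=lambda i: (i not in alpha, i))
        attach = Chem.MolFromSmiles(self.attach_smiles)
        if attach is None:
            raise chem.PatternError(self.attach_smiles, f"rule {self.name}")
        combined = Chem.RWMol(Chem.CombineMols(graph.mol, attach))
        combined.AddBond(site, graph.num_heavy_atoms, Chem.BondType.SINGLE)
        mol = combined.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
        return ChemicalGraph(mol)


@dataclass
class MonomerDatabase:
    entries: list[Monomer] = field(default_factory=list)
    skipped: int = 0  # records dropped at load time (unparsable SMILES)

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self.strict_index: dict[str, list[Monomer]] = {}
        self.light_index: dict[tuple, list[Monomer]] = {}
        self._alias_group: dict[str, str] = {}
        for m in self.entries:
            self.strict_index.setdefault(m.strict_key, []).append(m)
            self.light_index.setdefault(m.light_key, []).append(m)
            for alias in m.aliases:
                self._alias_group[alias] = m.code
        for index in (self.strict_index, self.light_index):
            for hits in index.values():
                hits.sort(key=lambda m: (m.origin != "database", m.code))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, code: str) -> Monomer | None:
        for m in self.entries:
            if m.code == code or code in m.aliases:
                return m
        return None

    def group_of(self, code: str) -> str:
        """Representative code of the isomer group containing ``code``
        (the code itself if unknown)."""
        return self._alias_group.get(code, code)

    def same_group(self, a: str, b: str) -> bool:
        return self.group_of(a) == self.group_of(b)


def group_isomers(entries: list[Monomer]) -> list[Monomer]:
    """Merge entries with identical stereo-stripped chemical graphs.

    The representative code is the lexicographically smallest member code; all
    member codes are kept as aliases. Entry order follows the first occurrence
    of each group.
    """
    groups: dict[str, list[Monomer]] = {}
    order: list[str] = []
    for m in entries:
        key = m.strict_key
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(m)
    merged = []
    for key in order:
        members = groups[key]
        codes = sorted({c for m in members for c in m.aliases})
        rep_code = codes[0]
        rep = min(members, key=lambda m: m.code)
        merged.append(replace(rep, code=rep_code, aliases=tuple(codes)))
    return merged


def _records_from_file(path: Path) -> list[dict]:
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if not isinstance(data, list):
            raise MonomerDBError(f"{path}: JSON monomer DB must be an array of records")
        return data
    records = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise MonomerDBError(f"{path}:{ln}: expected code<TAB>smiles, got {line!r}")
        records.append({"code": parts[0].strip(), "smiles": parts[1].strip()})
    return records


def load_database(path: str | Path) -> MonomerDatabase:
    """Load a monomer database from TSV (``code<TAB>smiles``) or a JSON array
    of ``{"code":…, "smiles":…}`` records.

    Records with unparsable SMILES are skipped with a warning (count kept on
    the database); duplicate codes with different structures are a hard error;
    stereoisomer duplicates are grouped into single entries.
    """
    path = Path(path)
    if not path.exists():
        raise MonomerDBError(f"monomer database not found: {path}")
    return database_from_records(_records_from_file(path))


def database_from_records(records: list[dict]) -> MonomerDatabase:
    entries: list[Monomer] = []
    seen: dict[str, str] = {}  # code -> strict key
    skipped = 0
    for rec in records:
        code, smiles = rec["code"], rec["smiles"]
        try:
            graph = chem.parse_smiles(smiles, record_id=code)
        except chem.ChemError as exc:
            warnings.warn(f"skipping monomer {code!r}: {exc}")
            skipped += 1
            continue
        key = chem.strict_key(graph)
        if code in seen:
            if seen[code] != key:
                raise MonomerDBError(
                    f"duplicate monomer code {code!r} with different structures"
                )
            continue
        seen[code] = key
        entries.append(Monomer(code=code, graph=graph))
    db = MonomerDatabase(entries=group_isomers(entries))
    db.skipped = skipped
    return db


def load_modification_rules(path: str | Path) -> list[ModificationRule]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        ModificationRule(
            name=r["name"], site_smarts=r["site_smarts"], attach_smiles=r["attach_smiles"]
        )
        for r in data
    ]


def default_modification_rules() -> list[ModificationRule]:
    """The shipped tailoring rules: N-methylation of a primary alpha-amine and
    N-formylation of a primary amine. Users extend the set via a JSON rule
    file with the same schema."""
    with resources.as_file(
        resources.files("nrpretro.data").joinpath("modification_rules.json")
    ) as p:
        return load_modification_rules(p)


def expand_modifications(
    db: MonomerDatabase, rules: list[ModificationRule]
) -> MonomerDatabase:
    """Derive new candidate monomers by applying tailoring rules to every
    database-origin entry.

    A derived entry is named ``<rule>-<code>``, flagged ``origin="derived"``,
    and skipped when its structure collides with anything already present —
    which also makes the expansion idempotent.
    """
    known = {m.strict_key for m in db.entries}
    new_entries = list(db.entries)
    for monomer in db.entries:
        if monomer.origin != "database":
            continue
        for rule in rules:
            derived_graph = rule.apply(monomer.graph)
            if derived_graph is None:
                continue
            if derived_graph.num_heavy_atoms <= monomer.graph.num_heavy_atoms:
                warnings.warn(
                    f"rule {rule.name!r} on {monomer.code!r} did not grow the graph; skipped"
                )
                continue
            key = chem.strict_key(derived_graph)
            if key in known:
                continue
            known.add(key)
            code = f"{rule.name}-{monomer.code}"
            new_entries.append(
                Monomer(
                    code=code,
                    graph=derived_graph,
                    aliases=(code,),
                    origin="derived",
                    derivation=(monomer.code, rule.name),
                )
            )
    out = MonomerDatabase(entries=new_entries)
    out.skipped = db.skipped
    return out


def packaged_database() -> MonomerDatabase:
    """The small monomer set shipped with the package: the 20 proteinogenic
    amino acids plus NRP-typical monomers (hydroxy acids, N-methyl variants,
    dehydro amino acids, aryl acids, ...)."""
    with resources.as_file(resources.files("nrpretro.data").joinpath("monomers.tsv")) as p:
        return load_database(p)
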