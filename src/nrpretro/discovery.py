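"""Monomer discovery: suggest new monomers for unannotated substructures.

After annotation, the repaired structure of every unmatched fragment is the
free-standing molecule a monomer database would store. Discovery groups these
by canonical SMILES across an input set, optionally resolves them to a name
and external identifier through a pluggable resolver, and reports them as
candidate new monomers together with the peptides containing them.

Resolvers: an offline JSON dictionary (the default; the only one used in
tests) and a live PubChem PUG-REST lookup for interactive use. Resolution
failures never abort a run — the suggestion is simply kept unresolved.
Discovery never alters coverage, the monomer graph or correctness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .fragmenter import FragmentationResult


@dataclass(frozen=True)
class Suggestion:
    smiles: str  # canonical SMILES of the unmatched repaired fragment
    resolved_name: str | None
    resolved_id: str | None
    peptides: tuple[str, ...]  # ids, with multiplicity

    @property
    def occurrence_count(self) -> int:
        return len(self.peptides)

    @property
    def multi_compound(self) -> bool:
        return len(set(self.peptides)) > 1


class OfflineResolver:
    """Resolver backed by a JSON map ``canonical-SMILES -> {name, id}``."""

    def __init__(self, mapping: dict | str | Path):
        if not isinstance(mapping, dict):
            mapping = json.loads(Path(mapping).read_text(encoding="utf-8"))
        self._mapping = mapping

    def resolve(self, smiles: str) -> tuple[str, str] | None:
        hit = self._mapping.get(smiles)
        if hit is None:
            return None
        if isinstance(hit, dict):
            return (hit.get("name"), hit.get("id"))
        return tuple(hit)


class PubChemResolver:  # pragma: no cover - network access, not used in tests
    """Identity-by-SMILES lookup against PubChem PUG-REST."""

    URL = (
        "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/smiles/"
        "{smiles}/property/IUPACName/JSON"
    )

    def __init__(self, timeout: float = 10.0):
        self.timeout = timeout

    def resolve(self, smiles: str) -> tuple[str, str] | None:
        import urllib.parse
        import urllib.request

        url = self.URL.format(smiles=urllib.parse.quote(smiles, safe=""))
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            data = json.loads(resp.read().decode())
        props = data["PropertyTable"]["Properties"][0]
        return (props.get("IUPACName"), f"CID:{props.get('CID')}")


def resolve(smiles: str, resolver) -> tuple[str, str] | None:
    """Apply a resolver, swallowing any failure (timeouts, missing entries):
    an unresolved suggestion is still a suggestion."""
    if resolver is None:
        return None
    try:
        return resolver.resolve(smiles)
    except Exception:
        return None


def aggregate(
    results: list[tuple[str, FragmentationResult]],
    resolver=None,
) -> list[Suggestion]:
    """Group the unmatched repaired fragments of an annotated input set by
    canonical SMILES; sort by occurrence count (descending), then SMILES."""
    groups: dict[str, list[str]] = {}
    for peptide_id, result in results:
        for af in result.unmatched:
            if af.repaired is None:
                continue
            smiles = af.repaired.canonical_smiles()
            groups.setdefault(smiles, []).append(peptide_id)
    suggestions = []
    for smiles in sorted(groups):
        resolved = resolve(smiles, resolver)
        suggestions.append(
            Suggestion(
                smiles=smiles,
                resolved_name=resolved[0] if resolved else None,
                resolved_id=resolved[1] if resolved else None,
                peptides=tuple(sorted(groups[smiles])),
            )
        )
    suggestions.sort(key=lambda s: (-s.occurrence_count, s.smiles))
    return suggestions


def report_json(suggestions: list[Suggestion]) -> str:
    return json.dumps(
        [
            {
                "smiles": s.smiles,
                "name": s.resolved_name,
                "id": s.resolved_id,
                "occurrences": s.occurrence_count,
                "multiCompound": s.multi_compound,
                "peptides": list(s.peptides),
            }
            for s in suggestions
        ],
        indent=2,
    )
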