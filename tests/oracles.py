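"""Independent brute-force oracles and corpus generators used by the tests.

Everything here stays deliberately independent of the engine's internals: the
subset oracle re-derives connectivity from the RDKit molecule itself and
enumerates candidate subsets exhaustively.
"""

from __future__ import annotations

import itertools
import random

from rdkit import Chem

from nrpretro.assemble import AssemblySpec, assemble


# -- exhaustive combination oracle ----------------------------------------


def _components_bruteforce(mol: Chem.Mol, removed_pairs: set[frozenset[int]]):
    adj = {a.GetIdx(): set() for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if frozenset((i, j)) in removed_pairs:
            continue
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def _islands(mol, candidates, subset) -> bool:
    removed = {
        frozenset(p) for i in subset for p in candidates[i].bond_pairs
    }
    comps = _components_bruteforce(mol, removed)
    return len(comps) > 1 and min(len(c) for c in comps) <= 2


def oracle_combinations(graph, candidates) -> set[frozenset[tuple]]:
    """Exhaustive maximal-subset-no-island enumeration, restricted by the
    amino/ester prioritization rule. Returns each combination as a frozenset
    of normalized cut-bond keys."""
    mol = graph.mol
    n = len(candidates)
    valid = []
    for r in range(n + 1):
        for subset in itertools.combinations(range(n), r):
            # a shared bond between two cuts is never valid
            pair_sets = [set(candidates[i].key) for i in subset]
            if any(
                pair_sets[a] & pair_sets[b]
                for a, b in itertools.combinations(range(len(subset)), 2)
            ):
                continue
            if _islands(mol, candidates, subset):
                continue
            valid.append(frozenset(subset))
    maximal = [s for s in valid if not any(s < t for t in valid)]

    # conflict components via union-find over conflicting pairs
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    conflicted = set()
    for i, j in itertools.combinations(range(n), 2):
        shared = set(candidates[i].key) & set(candidates[j].key)
        if shared or _islands(mol, candidates, (i, j)):
            conflicted.update((i, j))
            parent[find(i)] = find(j)
    components = {}
    for i in conflicted:
        components.setdefault(find(i), set()).add(i)
    for comp in components.values():
        if not any(candidates[i].pattern.prioritized for i in comp):
            continue
        filtered = [
            s
            for s in maximal
            if any(candidates[i].pattern.prioritized for i in s & comp)
        ]
        if filtered:
            maximal = filtered

    return {
        frozenset(candidates[i].key for i in s) for s in maximal
    }


# -- corpus generators -----------------------------------------------------

_SMALL_CODES = ["Gly", "Ala", "Ser", "Val", "Leu", "Lac", "Thr", "bAla", "Aib"]


def planted_molecules(db, n: int, seed: int, max_atoms: int = 30) -> list[str]:
    """Random small peptides with planted adjacent candidate bonds: amide
    N–H positions are randomly acylated, creating imide-style conflicts."""
    rng = random.Random(seed)
    out = []
    while len(out) < n:
        length = rng.randint(2, 3)
        seq = [rng.choice(_SMALL_CODES)]
        labels = []
        for _ in range(length - 1):
            label = "ESTER" if rng.random() < 0.2 else "AMINO"
            pool = ["Ser", "Thr", "Lac"] if label == "ESTER" else [
                c for c in _SMALL_CODES if c not in ("Lac",)
            ]
            labels.append(label)
            seq.append(rng.choice(pool))
        smiles, _ = assemble(AssemblySpec(tuple(seq), tuple(labels)), db)
        mol = Chem.MolFromSmiles(smiles)
        # random acylations: N-acylating an amine twice plants an imide whose
        # two amide cuts would strand the nitrogen; O-acylating a carboxyl
        # plants an anhydride whose two ester cuts would strand the oxygen
        site_patterns = [
            Chem.MolFromSmarts("[NX3;H2,H1]"),
            Chem.MolFromSmarts("[OX2H1]"),
        ]
        ok = True
        for _ in range(rng.randint(1, 3)):
            sites = sorted(
                {m[0] for patt in site_patterns for m in mol.GetSubstructMatches(patt)}
            )
            if not sites:
                break
            site = rng.choice(sites)
            em = Chem.RWMol(mol)
            c = em.AddAtom(Chem.Atom(6))
            o = em.AddAtom(Chem.Atom(8))
            me = em.AddAtom(Chem.Atom(6))
            em.AddBond(site, c, Chem.BondType.SINGLE)
            em.AddBond(c, o, Chem.BondType.DOUBLE)
            em.AddBond(c, me, Chem.BondType.SINGLE)
            acylated = em.GetMol()
            try:
                Chem.SanitizeMol(acylated)
            except Exception:
                ok = False
                break
            mol = acylated
        if ok and mol.GetNumAtoms() <= max_atoms:
            out.append(Chem.MolToSmiles(mol))
    return out


def decoy_monomers(n: int, seed: int) -> list[dict]:
    """Random valid amino-acid-like structures that cannot occur in any test
    peptide: every decoy carries at least one halogen, and no packaged
    monomer or assembled peptide contains any."""
    rng = random.Random(seed)
    chains = ["C", "CC", "CCC", "CCCC", "CCCCC", "C(C)C", "CC(C)C", "CCOC", "CCSC"]
    halo = ["F", "Cl", "Br"]
    seen, out = set(), []
    while len(out) < n:
        side = rng.choice(chains) + rng.choice(halo)
        smiles = f"NC(C{side})C(=O)O"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            # grow a random methyl to diversify
            side = rng.choice(chains) + rng.choice(chains) + rng.choice(halo)
            smiles = f"NC(C{side})C(=O)O"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
        seen.add(canonical)
        out.append({"code": f"dec{len(out):03d}", "smiles": canonical})
    return out
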