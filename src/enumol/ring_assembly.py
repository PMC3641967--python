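"""Ring-assembly extraction and deduplication.

A ring assembly is a maximal set of rings sharing at least one atom — a
fused, spiro or bridged ring system taken as one unit.  Ring systems joined
only through acyclic linkers (including a direct ring-ring single bond, as
in biphenyl) are separate assemblies.  Each assembly can optionally retain
its *alpha atoms*: the non-ring atoms directly bonded to a ring atom, kept
with their original element and bond order and hydrogen-capped.  Atoms
double-bonded to a ring atom (exocyclic carbonyls and the like) are always
kept as part of the assembly, since stripping them would alter the ring
atoms' hybridization.

Assemblies are identified by the canonical SMILES of the extracted,
H-capped subgraph, which is invariant to input atom ordering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from rdkit import Chem

__all__ = ["RingAssembly", "extract_assemblies", "dedupe_assemblies",
           "assembly_overlap"]


@dataclass(frozen=True)
class RingAssembly:
    key: str              # canonical SMILES of the extracted subgraph
    with_alpha: bool
    n_ring_atoms: int
    source_atoms: tuple   # parent-molecule atom indices included

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.key)


def _ring_systems(mol):
    """Connected ring systems as sets of atom indices (rings sharing >= 1
    atom are merged: fused, spiro and bridged all become one system)."""
    systems = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            systems.remove(s)
            ring |= s
        systems.append(ring)
    return systems


def _extract_submol(mol, keep: set) -> str:
    """Canonical SMILES of the induced subgraph over ``keep``, with
    leftover valences H-capped.

    Works on a kekulized copy so that partially kept aromatic systems (an
    aromatic alpha atom cut off from its own ring) stay valence-legal;
    aromaticity of intact rings is re-perceived on output.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    em = Chem.RWMol()
    index = {}
    for idx in sorted(keep):
        atom = kek.GetAtomWithIdx(idx)
        index[idx] = em.AddAtom(Chem.Atom(atom.GetSymbol()))
    for bond in kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in keep and j in keep:
            em.AddBond(index[i], index[j], bond.GetBondType())
    sub = em.GetMol()
    Chem.SanitizeMol(sub)
    return Chem.MolToSmiles(sub)


def extract_assemblies(mol, keep_alpha: bool = True):
    """Reduce a molecule to its list of ring assemblies.

    Acyclic molecules yield an empty list.  ``keep_alpha`` retains the
    directly bonded non-ring neighbors (one atom deep); exocyclic
    double-bonded partners are always retained.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    assemblies = []
    for system in _ring_systems(mol):
        keep = set(system)
        for idx in system:
            for bond in mol.GetAtomWithIdx(idx).GetBonds():
                nbr = bond.GetOtherAtomIdx(idx)
                if nbr in system:
                    continue
                if bond.GetBondType() == Chem.BondType.DOUBLE or keep_alpha:
                    keep.add(nbr)
        assemblies.append(RingAssembly(
            key=_extract_submol(mol, keep),
            with_alpha=keep_alpha,
            n_ring_atoms=len(system),
            source_atoms=tuple(sorted(keep)),
        ))
    return assemblies


def dedupe_assemblies(assemblies):
    """Group assemblies by canonical key.

    Returns a list of ``(key, count)`` pairs sorted by decreasing
    frequency (ties broken by key for determinism).
    """
    counts = Counter(a.key if isinstance(a, RingAssembly) else a
                     for a in assemblies)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def assembly_overlap(set_a, set_b):
    """Overlap of two deduplicated assembly sets.

    ``set_a``/``set_b`` are outputs of :func:`dedupe_assemblies`, plain key
    iterables, or :class:`RingAssembly` lists (which must share one
    ``with_alpha`` setting across both sets).  Returns a dict with the
    intersection keys, their count, and the fraction of ``set_a``'s unique
    assemblies that also occur in ``set_b``.
    """
    def norm(s):
        out, flags = {}, set()
        for item in s:
            if isinstance(item, RingAssembly):
                flags.add(item.with_alpha)
                out[item.key] = out.get(item.key, 0) + 1
            elif isinstance(item, tuple):
                out[item[0]] = item[1]
            else:
                out[item] = 1
        return out, flags

    a, flags_a = norm(set_a)
    b, flags_b = norm(set_b)
    if len(flags_a | flags_b) > 1:
        raise ValueError("assembly sets mix keep_alpha settings")
    common = sorted(set(a) & set(b))
    return {
        "keys": common,
        "n_common": len(common),
        "fraction_of_a": len(common) / len(a) if a else 0.0,
    }
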