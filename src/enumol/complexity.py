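"""Molecular-complexity (MC) scoring.

The score rewards topological features associated with structurally complex,
natural-product-like molecules: bridgehead atoms, spiro atoms, potential
stereocenters, mid/large rings and non-aromatic double bonds each contribute
a log10(count + 1) term, plus a slowly saturating size term
n_heavy * 1.005**(-n_heavy) that peaks near 200 heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from math import log10

__all__ = ["ComplexityCounts", "complexity_counts", "mc_score",
           "MID_LARGE_RING_MIN_SIZE"]

#: Macrocycle convention: rings of this size or larger count as mid/large.
MID_LARGE_RING_MIN_SIZE = 8


@dataclass(frozen=True)
class ComplexityCounts:
    n_bridge_atoms: int
    n_spiro_atoms: int
    n_stereo_centers: int
    n_mid_large_rings: int
    n_non_aromatic_double_bonds: int
    n_heavy_atoms: int

    def to_dict(self):
        return asdict(self)


def complexity_counts(mol, min_large_ring: int = MID_LARGE_RING_MIN_SIZE
                      ) -> ComplexityCounts:
    """Topology counts feeding the MC score.

    Stereocenters are *potential* tetrahedral centers (perceived, not
    assigned); bridgehead/spiro atoms use the standard ring-topology
    definitions; rings come from the smallest set of smallest rings.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    n_stereo = len(Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False))
    n_large = sum(1 for ring in mol.GetRingInfo().AtomRings()
                  if len(ring) >= min_large_ring)
    n_double = sum(1 for b in mol.GetBonds()
                   if b.GetBondType() == Chem.BondType.DOUBLE
                   and not b.GetIsAromatic())
    return ComplexityCounts(
        n_bridge_atoms=rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        n_spiro_atoms=rdMolDescriptors.CalcNumSpiroAtoms(mol),
        n_stereo_centers=n_stereo,
        n_mid_large_rings=n_large,
        n_non_aromatic_double_bonds=n_double,
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
    )


def mc_score(counts: ComplexityCounts, size_term: str = "damped") -> float:
    """MC = sum of log10(count+1) over the five feature counts plus a size
    term.

    ``size_term="damped"`` (default) uses n_heavy * 1.005**(-n_heavy), an
    increasing, slowly saturating reward over the drug-size range.  The
    alternative ``"power"`` reading, n_heavy**(1.005 - n_heavy), vanishes
    for any drug-sized molecule and is kept only for comparison.
    """
    log_sum = (log10(counts.n_bridge_atoms + 1)
               + log10(counts.n_spiro_atoms + 1)
               + log10(counts.n_stereo_centers + 1)
               + log10(counts.n_mid_large_rings + 1)
               + log10(counts.n_non_aromatic_double_bonds + 1))
    n = counts.n_heavy_atoms
    if size_term == "damped":
        size = n * 1.005 ** (-n)
    elif size_term == "power":
        size = 0.0 if n == 0 else n ** (1.005 - n)
    else:
        raise ValueError(f"unknown size_term {size_term!r}")
    return log_sum + size
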