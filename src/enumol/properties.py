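"""Physicochemical profiling: the six bulk properties, drug-likeness rules,
Fsp3, and set-level summaries.

Property conventions follow the desk-standard realizations: molecular weight
from average atomic masses, polar surface area as Ertl topological PSA,
AlogP as the Crippen atom-contribution logP, hydrogen-bond acceptor/donor
counts by the original Lipinski N+O / N-H+O-H convention, and rotatable
bonds as non-ring single bonds between non-terminal heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = ["PropertyVector", "SetSummary", "compute_properties",
           "lipinski_compliant", "veber_compliant", "summarize_set",
           "as_frame"]


@dataclass(frozen=True)
class PropertyVector:
    mw: float          # g/mol
    psa: float         # Angstrom^2 (topological)
    alogp: float
    hba: int           # Lipinski N+O count
    hbd: int           # Lipinski NH+OH count
    rotb: int
    n_heavy: int
    fsp3: float        # sp3 carbons / total carbons (0 when no carbons)

    #: the six properties used for property-space similarity
    MFS_FIELDS = ("mw", "psa", "alogp", "hba", "hbd", "rotb")

    def mfs_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.MFS_FIELDS],
                        dtype=float)


def compute_properties(mol) -> PropertyVector:
    """Property vector of a molecule (RDKit Mol or SMILES string)."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        alogp=Crippen.MolLogP(mol),
        hba=rdMolDescriptors.CalcNumLipinskiHBA(mol),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
    )


def lipinski_compliant(pv: PropertyVector, max_violations: int = 0) -> bool:
    """Rule-of-five check; ``max_violations=1`` enables the common
    one-violation allowance (the default is the strict zero-violation
    reading)."""
    violations = sum([pv.mw > 500.0, pv.alogp > 5.0,
                      pv.hbd > 5, pv.hba > 10])
    return violations <= max_violations


def veber_compliant(pv: PropertyVector) -> bool:
    """Oral-bioavailability rule: rotatable bonds <= 10 and PSA <= 140 A^2
    (boundaries inclusive)."""
    return pv.rotb <= 10 and pv.psa <= 140.0


def as_frame(vectors) -> "pandas.DataFrame":
    import pandas as pd
    return pd.DataFrame([asdict(v) for v in vectors])


@dataclass(frozen=True)
class SetSummary:
    n: int
    mean: dict
    sd: dict
    fraction_mw_lt_500: float
    fraction_mw_200_500: float
    fraction_mw_200_500_psa_0_140: float
    fraction_lipinski: float
    fraction_veber: float
    fraction_both: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_set(vectors, max_lipinski_violations: int = 0) -> SetSummary:
    """Set-level summary of property vectors.

    MW windows are boundary-inclusive; the PSA window of the combined
    MW/PSA fraction is strict (0 < PSA < 140).
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("empty property-vector set")
    fields = ("mw", "psa", "alogp", "hba", "hbd", "rotb", "n_heavy", "fsp3")
    cols = {f: np.array([getattr(v, f) for v in vectors], dtype=float)
            for f in fields}
    mw, psa = cols["mw"], cols["psa"]
    lip = np.array([lipinski_compliant(v, max_lipinski_violations)
                    for v in vectors])
    veb = np.array([veber_compliant(v) for v in vectors])
    in_mw = (mw >= 200.0) & (mw <= 500.0)
    return SetSummary(
        n=len(vectors),
        mean={f: float(c.mean()) for f, c in cols.items()},
        sd={f: float(c.std()) for f, c in cols.items()},
        fraction_mw_lt_500=float(np.mean(mw < 500.0)),
        fraction_mw_200_500=float(np.mean(in_mw)),
        fraction_mw_200_500_psa_0_140=float(
            np.mean(in_mw & (psa > 0.0) & (psa < 140.0))),
        fraction_lipinski=float(lip.mean()),
        fraction_veber=float(veb.mean()),
        fraction_both=float((lip & veb).mean()),
    )
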