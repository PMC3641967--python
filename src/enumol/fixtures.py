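"""Synthetic test inputs: a toy molecule deck with frozen expected values
and analytic point-set conformers with closed-form shape expectations.

Everything here is generated in code — no external data.  The analytic
conformers bypass 3D embedding entirely, so the shape mathematics can be
exercised independently of the embedding stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shape import Conformer

__all__ = ["ToyEntry", "toy_molecule_deck", "analytic_conformers"]


@dataclass(frozen=True)
class ToyEntry:
    name: str
    smiles: str
    #: expected values; each key maps to (value, provenance-tag)
    expected: dict = field(default_factory=dict)


def toy_molecule_deck():
    """Ten small molecules with hand-checked expected values.

    Provenance tags: "trivial" = immediate from the definition;
    "derived" = computed once with the named independent oracle (direct
    arithmetic, contribution tables) and frozen here.
    """
    return [
        ToyEntry("methane", "C", {
            "mw": (16.043, "derived: atomic masses 12.011 + 4*1.008"),
            "psa": (0.0, "trivial"),
            "hba": (0, "trivial"), "hbd": (0, "trivial"),
            "rotb": (0, "trivial"), "fsp3": (1.0, "trivial"),
            "mc": (0.99502, "derived: 1 * 1.005**-1"),
            "n_assemblies": (0, "trivial"),
        }),
        ToyEntry("ethanol", "CCO", {
            "hba": (1, "trivial"), "hbd": (1, "trivial"),
            "psa": (20.23, "derived: Ertl TPSA hydroxyl contribution"),
            "n_assemblies": (0, "trivial"),
        }),
        ToyEntry("benzene", "c1ccccc1", {
            "fsp3": (0.0, "trivial"), "rotb": (0, "trivial"),
            "mc": (5.8231, "derived: 6 * 1.005**-6"),
            "n_assemblies": (1, "trivial"),
            "npr_disc": (True, "trivial: planar sixfold symmetry -> "
                               "(0.5, 0.5) moment pattern"),
        }),
        ToyEntry("toluene", "Cc1ccccc1", {
            "n_assemblies": (1, "trivial"),
            "assembly_no_alpha": ("c1ccccc1", "trivial"),
            "assembly_with_alpha": ("Cc1ccccc1", "trivial"),
        }),
        ToyEntry("decalin", "C1CCC2CCCCC2C1", {
            "n_assemblies": (1, "trivial: fused bicyclic"),
            "fsp3": (1.0, "trivial"),
        }),
        ToyEntry("adamantane", "C1C2CC3CC1CC(C2)C3", {
            "n_assemblies": (1, "trivial"),
            "sphere_like": (True, "derived: embedded conformer NPRs > 0.9"),
            "n_bridge_atoms": (4, "trivial: four CH bridgeheads"),
        }),
        ToyEntry("spiro[4.4]nonane", "C1CCC2(C1)CCCC2", {
            "n_spiro_atoms": (1, "trivial: by construction"),
            "n_heavy": (9, "trivial"),
            "n_assemblies": (1, "trivial"),
        }),
        ToyEntry("cyclooctane", "C1CCCCCCC1", {
            "n_mid_large_rings": (1, "trivial: ring size 8 threshold"),
            "n_assemblies": (1, "trivial"),
        }),
        ToyEntry("biphenyl", "c1ccc(-c2ccccc2)cc1", {
            "n_assemblies": (2, "trivial: directly bonded unfused rings "
                                "are separate assemblies"),
        }),
        ToyEntry("cyclohexylbenzene", "C1CCC(CC1)c1ccccc1", {
            "n_assemblies": (2, "trivial"),
        }),
    ]


def _regular_polygon(n, radius=1.0):
    angles = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(angles), radius * np.sin(angles),
                     np.zeros(n)], axis=1)


def analytic_conformers():
    """Point-set conformers with closed-form PMI expectations.

    Returns a dict: rod (collinear equal masses, NPR -> (0, 1)), disc
    (regular hexagon: in-plane moments are half the perpendicular one, so
    NPR = (0.5, 0.5)), sphere (regular tetrahedron, NPR = (1, 1)), icosahedron
    (NPR = (1, 1)), and a x2-scaled copy of each for size-invariance
    checks.
    """
    rod = np.zeros((7, 3))
    rod[:, 0] = np.linspace(-3.0, 3.0, 7)
    tetra = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                      [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    phi = (1 + 5 ** 0.5) / 2
    ico = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                    [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                    [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                   dtype=float)
    base = {
        "rod": Conformer.from_points(rod),
        "disc": Conformer.from_points(_regular_polygon(6, radius=1.4)),
        "sphere": Conformer.from_points(tetra),
        "icosahedron": Conformer.from_points(ico),
    }
    scaled = {f"{k}_x2": v.scaled(2.0) for k, v in base.items()}
    return {**base, **scaled}
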