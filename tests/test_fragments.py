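"""Fragment library: default contents, weight scaling, site compatibility."""

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from enumol.enumerator import EnumeratorConfig, enumerate_one
import numpy as np

from enumol.fragments import (FragmentLibrary, LibraryError,
                              compatible_fragments, default_library,
                              scale_weight)


def test_default_library_contents():
    lib = default_library()
    assert len(lib) == 10
    assert lib.get("Phenyl (*C1,C2^D)").weight == 1
    for frag in lib:
        if not frag.is_hydrogen_cap and len(frag.atoms) <= 2 \
                and frag.carbon_count <= 1:
            assert frag.weight == 6
    with_olefin = default_library(include_olefin=True)
    assert len(with_olefin) == 11
    assert with_olefin.get("*C=C^P").weight == 3
    assert with_olefin.get("*C=C^P").allow_heteroatom_attachment == "no"


@pytest.mark.parametrize("label, expected", [
    ("Phenyl (*C1,C2^D)", 1.0),
    ("*C=C^P", 3.0),
    ("H", 6.0),
    ("*O^P", 6.0),
    ("^P*C-O", 6.0),
])
def test_weight_scaling_reproduces_table(label, expected):
    lib = default_library(include_olefin=True)
    assert scale_weight(lib.get(label), lib.max_carbon_count) == expected


def test_weight_scaling_rejects_bad_reference():
    lib = default_library()
    with pytest.raises(LibraryError):
        scale_weight(lib.get("H"), 0)


def test_nitrogen_site_excludes_flagged_fragments():
    lib = default_library()
    labels = {f.label for f in compatible_fragments(lib, "N", 1)}
    assert {"*N^P", "*O^T", "*O^P", "^P*C-O"}.isdisjoint(labels)
    assert {"H", "*C^P", "^A*C=O"} <= labels


def test_carbon_site_accepts_all_single_order_fragments():
    lib = default_library()
    labels = {f.label for f in compatible_fragments(lib, "C", 1)}
    # free valence 1 excludes only the double-bond carbonyl oxygen
    assert labels == {f.label for f in lib} - {"*O^D"}


def test_double_bond_fragment_needs_capable_site():
    lib = default_library()
    assert "*O^D" in {f.label for f in
                      compatible_fragments(lib, "C", 2,
                                           site_accepts_double=True)}
    assert "*O^D" not in {f.label for f in
                          compatible_fragments(lib, "C", 2,
                                               site_accepts_double=False)}


def test_h_only_library_is_always_compatible():
    lib = FragmentLibrary([default_library().get("H")], name="h-only")
    assert [f.label for f in compatible_fragments(lib, "N", 1)] == ["H"]


def test_library_yaml_round_trip_is_bit_exact(tmp_path):
    lib = default_library(include_olefin=True)
    path = tmp_path / "library.yaml"
    lib.save(path)
    loaded = FragmentLibrary.load(path)
    assert loaded.to_yaml() == lib.to_yaml()
    assert [f.label for f in loaded] == [f.label for f in lib]
    assert [f.weight for f in loaded] == [f.weight for f in lib]


def test_each_fragment_caps_to_valid_molecule():
    """A library of one fragment plus H grows into a parseable, valence
    legal molecule (RDKit sanitization would reject violations)."""
    full = default_library(include_olefin=True)
    h = full.get("H")
    for frag in full:
        if frag.is_hydrogen_cap:
            continue
        lib = FragmentLibrary([h, frag], name=f"solo-{frag.label}")
        cfg = EnumeratorConfig(library=lib, h_weight_multiplier=0.5,
                               ring_closure_probability=0.0,
                               max_growth_cycles=5)
        rng = np.random.Generator(np.random.PCG64(3))
        mol = enumerate_one(cfg, rng)
        smi = mol.to_smiles()
        assert Chem.MolFromSmiles(smi) is not None


@settings(max_examples=100, derandomize=True)
@given(element=st.sampled_from(["C", "N", "O"]),
       fv=st.integers(min_value=1, max_value=3),
       accepts_double=st.booleans())
def test_compatibility_never_violates_heteroatom_flag(element, fv,
                                                      accepts_double):
    lib = default_library(include_olefin=True)
    for frag in compatible_fragments(lib, element, fv, accepts_double):
        if element in ("N", "O") and not frag.is_hydrogen_cap:
            assert frag.allow_heteroatom_attachment == "yes"
        assert frag.is_hydrogen_cap or frag.attach_order() <= fv
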