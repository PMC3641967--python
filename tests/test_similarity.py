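"""Fingerprints, Tanimoto/Euclidean similarity and fusion statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enumol.properties import compute_properties
from enumol.similarity import (Fingerprint, PropertyStandardizer,
                               exact_hit_rate, fingerprint,
                               internal_diversity, mfs_map,
                               property_distance, tanimoto)


def _fp(*features):
    return Fingerprint(frozenset(features), len(features))


def test_tanimoto_examples():
    assert tanimoto(_fp(1, 2, 3), _fp(1, 2, 3)) == 1.0
    assert tanimoto(_fp(1, 2), _fp(3, 4)) == 0.0
    assert tanimoto(_fp(1, 2, 3), _fp(2, 3, 4)) == 0.5
    assert tanimoto(_fp(), _fp()) == 1.0  # degenerate both-empty


def test_fingerprint_determinism_and_symmetry():
    a, b = fingerprint("CCO"), fingerprint("CCN")
    assert fingerprint("CCO").features == a.features
    assert tanimoto(a, b) == tanimoto(b, a)
    assert 0.0 <= tanimoto(a, b) <= 1.0


def test_property_distance_identity_and_symmetry(small_run):
    pvs = [compute_properties(r.smiles) for r in small_run[:40]]
    std = PropertyStandardizer(pvs)
    assert property_distance(pvs[0], pvs[0], std) == 0.0
    d_ab = property_distance(pvs[0], pvs[1], std)
    assert d_ab == property_distance(pvs[1], pvs[0], std)
    assert d_ab >= 0.0


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=-5, max_value=5), min_size=18,
                max_size=18))
def test_property_distance_triangle_inequality(values):
    ref = [np.arange(6) * 1.0, np.arange(6) * 2.0 + 1, np.arange(6) ** 2]
    std = PropertyStandardizer(ref)
    a, b, c = (np.array(values[k:k + 6]) for k in (0, 6, 12))
    assert (property_distance(a, c, std)
            <= property_distance(a, b, std)
            + property_distance(b, c, std) + 1e-9)


def test_standardizer_drops_zero_variance_property():
    ref = [np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
           np.array([2.0, 2.0, 4.0, 5.0, 6.0, 7.0])]
    with pytest.warns(UserWarning, match="psa"):
        std = PropertyStandardizer(ref)
    assert std.transform(ref[0]).shape == (5,)


def test_mfs_ordering_and_self_match(small_run):
    smiles = [r.smiles for r in small_run[:30]]
    fps = [fingerprint(s) for s in smiles]
    records = mfs_map(fps, fps)
    for rec in records:
        assert rec.min_tanimoto <= rec.mean_tanimoto <= rec.max_tanimoto
        assert rec.max_tanimoto == 1.0  # query set == reference set


def test_mfs_single_reference_collapses_fusion():
    fps = [fingerprint("CCO"), fingerprint("CCCN")]
    records = mfs_map(fps, [fingerprint("CCC")])
    for rec in records:
        assert rec.min_tanimoto == rec.mean_tanimoto == rec.max_tanimoto


def test_mfs_with_properties(small_run):
    smiles = [r.smiles for r in small_run[:20]]
    fps = [fingerprint(s) for s in smiles]
    pvs = [compute_properties(s) for s in smiles]
    records = mfs_map(fps, fps, pvs, pvs)
    for rec in records:
        assert rec.min_euclidean == pytest.approx(0.0, abs=1e-9)
        assert rec.mean_euclidean >= rec.min_euclidean


def test_exact_hit_rate_subset_is_one():
    ref = [fingerprint(s) for s in ("CCO", "CCC", "c1ccccc1")]
    rate, pairs = exact_hit_rate(ref[:2], ref)
    assert rate == 1.0
    assert (0, 0) in pairs and (1, 1) in pairs


def test_exact_hit_rate_disjoint_is_zero():
    rate, pairs = exact_hit_rate([fingerprint("CCO")],
                                 [fingerprint("c1ccccc1")])
    assert rate == 0.0 and pairs == []


def test_exact_hit_rate_arithmetic():
    # one matching query among 625 mirrors a 0.16% hit rate
    ref = [fingerprint("CCO")]
    queries = [_fp(i) for i in range(624)] + ref
    rate, _ = exact_hit_rate(queries, ref)
    assert rate == pytest.approx(0.0016, abs=1e-6)


def test_internal_diversity_identical_set():
    fps = [fingerprint("c1ccccc1")] * 5
    summary = internal_diversity(fps)
    assert summary["median"] == 0.0 and summary["max"] == 0.0
    assert summary["n_pairs"] == 10


def test_internal_diversity_summary_invariants(small_run):
    fps = [fingerprint(r.smiles) for r in small_run[:80]]
    summary = internal_diversity(fps)
    assert summary["q1"] <= summary["median"] <= summary["q3"]
    assert summary["median"] <= summary["max"] <= 1.0
    assert not summary["subsampled"]


def test_internal_diversity_subsampling_flag(small_run):
    fps = [fingerprint(r.smiles) for r in small_run[:60]]
    summary = internal_diversity(fps, max_n=30, seed=4)
    assert summary["subsampled"] and summary["n"] == 30


def test_internal_diversity_rejects_singleton():
    with pytest.raises(ValueError):
        internal_diversity([fingerprint("CCO")])
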