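"""Fingerprint and property-space similarity analysis.

Structural similarity uses hashed circular substructure fingerprints of
radius 2 (ECFP_4-equivalent Morgan features) compared by the Tanimoto
index; property-space similarity uses Euclidean distance between
standardized six-property vectors (MW, PSA, AlogP, HBA, HBD, RotB).
Multi-fusion similarity condenses each query's similarities against an
entire reference set into min/mean/max fusion statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .properties import PropertyVector

__all__ = ["Fingerprint", "FusionRecord", "PropertyStandardizer",
           "fingerprint", "tanimoto", "property_distance", "mfs_map",
           "exact_hit_rate", "internal_diversity"]

_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2)


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular fingerprint: the set of hashed environment ids."""
    features: frozenset
    n_bits: int

    @property
    def is_empty(self) -> bool:
        return not self.features


def fingerprint(mol) -> Fingerprint:
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    features = frozenset(
        _GEN.GetSparseCountFingerprint(mol).GetNonzeroElements())
    return Fingerprint(features, len(features))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; defined as 1.0 when both fingerprints are empty
    (two featureless molecules are indistinguishable)."""
    fa = a.features if isinstance(a, Fingerprint) else frozenset(a)
    fb = b.features if isinstance(b, Fingerprint) else frozenset(b)
    if not fa and not fb:
        return 1.0
    inter = len(fa & fb)
    return inter / (len(fa) + len(fb) - inter)


class PropertyStandardizer:
    """Per-property mean/SD fitted on a reference set; zero-SD properties
    are dropped from the distance with a warning."""

    def __init__(self, reference):
        matrix = np.array([(p.mfs_vector() if isinstance(p, PropertyVector)
                            else np.asarray(p, dtype=float))
                           for p in reference])
        if matrix.ndim != 2 or len(matrix) == 0:
            raise ValueError("empty reference set")
        self.mean = matrix.mean(axis=0)
        self.sd = matrix.std(axis=0)
        self.active = self.sd > 0
        if not self.active.all():
            dropped = [PropertyVector.MFS_FIELDS[i]
                       for i in np.nonzero(~self.active)[0]]
            warnings.warn(f"zero-variance properties excluded from "
                          f"distance: {dropped}")

    def transform(self, pv) -> np.ndarray:
        v = (pv.mfs_vector() if isinstance(pv, PropertyVector)
             else np.asarray(pv, dtype=float))
        return (v[self.active] - self.mean[self.active]) / self.sd[self.active]


def property_distance(a, b, standardizer: PropertyStandardizer) -> float:
    """Euclidean distance between standardized six-property vectors."""
    return float(np.linalg.norm(standardizer.transform(a)
                                - standardizer.transform(b)))


@dataclass(frozen=True)
class FusionRecord:
    index: int
    min_tanimoto: float
    mean_tanimoto: float
    max_tanimoto: float
    min_euclidean: float | None
    mean_euclidean: float | None

    def to_dict(self):
        return asdict(self)


def mfs_map(query_fps, reference_fps, query_pvs=None, reference_pvs=None,
            standardizer: PropertyStandardizer | None = None):
    """Multi-fusion similarity records: per query, fusion statistics of
    Tanimoto similarity (and, when property vectors are supplied,
    standardized Euclidean distance) against the whole reference set.

    The property standardizer defaults to one fitted on the reference set.
    """
    reference_fps = list(reference_fps)
    if not reference_fps:
        raise ValueError("empty reference set")
    with_props = query_pvs is not None and reference_pvs is not None
    if with_props and standardizer is None:
        standardizer = PropertyStandardizer(reference_pvs)
    ref_feature_sets = [fp.features for fp in reference_fps]
    ref_std = ([standardizer.transform(p) for p in reference_pvs]
               if with_props else None)
    records = []
    for i, fp in enumerate(query_fps):
        sims = np.array([tanimoto(fp, r) for r in reference_fps])
        if with_props:
            q = standardizer.transform(query_pvs[i])
            d = np.array([np.linalg.norm(q - r) for r in ref_std])
            min_e, mean_e = float(d.min()), float(d.mean())
        else:
            min_e = mean_e = None
        records.append(FusionRecord(i, float(sims.min()), float(sims.mean()),
                                    float(sims.max()), min_e, mean_e))
    return records


def exact_hit_rate(query_fps, reference_fps):
    """Fraction of queries with a Tanimoto of exactly 1.0 against the
    reference set (identical feature sets), plus the matching pairs."""
    query_fps = list(query_fps)
    ref_index = {}
    for j, fp in enumerate(reference_fps):
        ref_index.setdefault(fp.features, []).append(j)
    pairs = []
    hits = 0
    for i, fp in enumerate(query_fps):
        matches = ref_index.get(fp.features)
        if matches:
            hits += 1
            pairs.extend((i, j) for j in matches)
    rate = hits / len(query_fps) if query_fps else 0.0
    return rate, pairs


def internal_diversity(fps, max_n: int = 5000, seed: int = 0):
    """All-pairs Tanimoto-distance (1 - similarity) summary of a set.

    Sets larger than ``max_n`` are deterministically subsampled (seeded)
    before the O(n^2) computation; the summary flags when that happened.
    """
    fps = list(fps)
    if len(fps) < 2:
        raise ValueError("need at least 2 items for internal diversity")
    subsampled = len(fps) > max_n
    if subsampled:
        idx = np.random.Generator(np.random.PCG64(seed)).choice(
            len(fps), size=max_n, replace=False)
        fps = [fps[i] for i in sorted(idx)]
    feats = [fp.features for fp in fps]
    sizes = np.array([len(f) for f in feats])
    # sparse occurrence matrix; A @ A.T gives all pairwise intersections
    feature_ids = {f: k for k, f in
                   enumerate(sorted(set().union(*feats) or set()))}
    rows = np.repeat(np.arange(len(feats)), sizes)
    cols = np.array([feature_ids[f] for fs in feats for f in sorted(fs)],
                    dtype=np.int64) if feature_ids else np.array([], int)
    from scipy import sparse
    a = sparse.csr_matrix(
        (np.ones(len(cols), dtype=np.int32), (rows, cols)),
        shape=(len(feats), max(1, len(feature_ids))))
    gram = sparse.triu(a @ a.T, k=1).tocoo()
    n = len(feats)
    n_pairs = n * (n - 1) // 2
    union = sizes[gram.row] + sizes[gram.col] - gram.data
    nondisjoint = 1.0 - np.where(union == 0, 1.0, gram.data / union)
    # pairs absent from the gram matrix share no feature: distance exactly 1
    # (or 0 for two empty fingerprints, handled by the union==0 branch)
    empty = sizes == 0
    n_empty_pairs = int(empty.sum()) * (int(empty.sum()) - 1) // 2
    dists = np.concatenate([
        nondisjoint,
        np.zeros(n_empty_pairs),
        np.ones(n_pairs - len(nondisjoint) - n_empty_pairs),
    ])
    q1, med, q3 = np.percentile(dists, [25, 50, 75])
    return {"n": len(fps), "n_pairs": len(dists), "subsampled": subsampled,
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "mean": float(dists.mean()), "max": float(dists.max())}
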