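"""3D shape description.

Two families of shape descriptors are computed from a single embedded
conformer per molecule:

* the normalized principal moments of inertia (NPR1 = I1/I3,
  NPR2 = I2/I3), which place a molecule inside the rod-disc-sphere
  isosceles triangle with vertices (0, 1), (0.5, 0.5) and (1, 1);
* the aggregate-shape parameters borrowed from petrology: elongation
  p = small/medium and flatness q = medium/large of a sorted size triple
  (computed from both the PMI triple and the triple of principal-plane
  shadow areas), plus sphericity

      psi = (surface area of the sphere with the molecule's volume) / SASA
          = pi**(1/3) * (6 * V)**(2/3) / SASA,

  where SASA is the solvent-accessible surface area at a 1.4 Angstrom
  probe and V, by default, is the volume enclosed by that same
  solvent-accessible surface (probe-inflated atomic spheres), so that a
  single sphere scores exactly 1; a bare-vdW-volume variant is available.

All geometry is computed from plain coordinate/radius/mass arrays
(:class:`Conformer`), so analytic point sets can exercise the math without
any embedding; :func:`embed_conformer` produces conformers for real
molecules by seeded distance-geometry embedding plus force-field
relaxation.

A five-descriptor PCA (p and q from both triples, plus psi) maps a
collection of ring assemblies onto a scaled 50x50 frequency grid for
chemical shape-space comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "Conformer", "ShapeDescriptors", "ShapeMap",
    "embed_conformer", "principal_moments", "shadow_areas",
    "elongation_flatness", "sphericity", "sphericity_from_volume_area",
    "vdw_volume", "sasa", "shape_descriptors",
    "shape_pca_fit", "shape_map_project", "pmi_triangle",
]

_PT = Chem.GetPeriodicTable()

DEFAULT_PROBE_RADIUS = 1.4     # Angstrom, water probe
DEFAULT_RASTER_PITCH = 0.2     # Angstrom, shadow-area rasterization
DEFAULT_VOXEL_PITCH = 0.35     # Angstrom, vdW volume grid
DEFAULT_SASA_POINTS = 960      # Shrake-Rupley sphere points
GRID_SIZE = 50


@dataclass
class Conformer:
    """One 3D conformer as plain arrays (Angstrom; unified atomic masses)."""
    coords: np.ndarray            # (n, 3)
    elements: tuple
    radii: np.ndarray             # vdW radii
    masses: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @classmethod
    def from_points(cls, coords, radius=1.7, mass=12.011, element="C"):
        """Analytic point-set conformer with uniform radii and masses."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        return cls(coords, (element,) * n, np.full(n, float(radius)),
                   np.full(n, float(mass)), {"source": "points"})

    @classmethod
    def from_rdkit(cls, mol, conf_id: int = -1, provenance=None):
        conf = mol.GetConformer(conf_id)
        coords = conf.GetPositions()
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        radii = np.array([_PT.GetRvdw(a.GetAtomicNum())
                          for a in mol.GetAtoms()])
        masses = np.array([a.GetMass() for a in mol.GetAtoms()])
        return cls(coords, elements, radii, masses, provenance or {})

    def scaled(self, factor: float) -> "Conformer":
        """Uniformly scaled copy (coordinates and radii)."""
        return Conformer(self.coords * factor, self.elements,
                         self.radii * factor, self.masses,
                         dict(self.provenance, scaled=factor))


class EmbeddingError(RuntimeError):
    pass


def molecule_embed_seed(mol_or_smiles) -> int:
    """Stable per-molecule embedding seed derived from canonical SMILES."""
    smi = (mol_or_smiles if isinstance(mol_or_smiles, str)
           else Chem.MolToSmiles(mol_or_smiles))
    return int.from_bytes(hashlib.sha256(smi.encode()).digest()[:4],
                          "big") % (2 ** 31 - 1)


def embed_conformer(mol, seed: int | None = None, n_confs: int = 5,
                    optimize: bool = True) -> Conformer:
    """Embed one conformer: best-energy pick of ``n_confs`` seeded
    distance-geometry embeddings, each relaxed with MMFF94 (UFF fallback).

    Deterministic for a given (molecule, seed); raises
    :class:`EmbeddingError` when no embedding succeeds.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise EmbeddingError("unparseable SMILES")
    if seed is None:
        seed = molecule_embed_seed(mol)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if len(ids) == 0:
        raise EmbeddingError(f"embedding failed for "
                             f"{Chem.MolToSmiles(mol)}")
    energies = {}
    if optimize:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            results = AllChem.MMFFOptimizeMoleculeConfs(molh)
        else:
            results = AllChem.UFFOptimizeMoleculeConfs(molh)
        for cid, (converged, energy) in zip(ids, results):
            energies[cid] = energy
    best = min(ids, key=lambda cid: energies.get(cid, 0.0))
    return Conformer.from_rdkit(
        molh, best, {"seed": int(seed), "n_confs": n_confs,
                     "relaxation": "MMFF94/UFF" if optimize else "none"})


# --------------------------------------------------------------------------
# moments, shadows, p/q, sphericity
# --------------------------------------------------------------------------

def _inertia_tensor(conf: Conformer):
    m = conf.masses
    x = conf.coords - np.average(conf.coords, axis=0, weights=m)
    r2 = (x ** 2).sum(axis=1)
    t = np.zeros((3, 3))
    t[np.diag_indices(3)] = (m[:, None] * (r2[:, None] - x ** 2)).sum(axis=0)
    for a in range(3):
        for b in range(a + 1, 3):
            off = -(m * x[:, a] * x[:, b]).sum()
            t[a, b] = t[b, a] = off
    return t, x


def principal_moments(conf: Conformer):
    """Mass-weighted principal moments of inertia, ascending.

    Returns ``(I1, I2, I3), (npr1, npr2)`` with I in amu * Angstrom^2.
    """
    t, _ = _inertia_tensor(conf)
    moments = np.linalg.eigvalsh(t)
    moments = np.clip(moments, 0.0, None)
    i1, i2, i3 = moments
    if i3 <= 0:  # single atom / all coincident: define as perfect sphere
        return tuple(moments), (1.0, 1.0)
    return tuple(moments), (i1 / i3, i2 / i3)


def principal_axes_coords(conf: Conformer) -> np.ndarray:
    """Centered coordinates rotated into the principal inertia frame."""
    t, x = _inertia_tensor(conf)
    _, vecs = np.linalg.eigh(t)
    return x @ vecs


def shadow_areas(conf: Conformer, pitch: float = DEFAULT_RASTER_PITCH):
    """Areas of the molecule's projections onto the three principal
    planes, ascending (Angstrom^2).

    Each projection is the union of atomic vdW disks, rasterized at
    ``pitch`` resolution.
    """
    x = principal_axes_coords(conf)
    areas = []
    for drop in range(3):
        keep = [a for a in range(3) if a != drop]
        pts = x[:, keep]
        r = conf.radii
        lo = (pts - r[:, None]).min(axis=0) - pitch
        hi = (pts + r[:, None]).max(axis=0) + pitch
        nx = max(2, int(np.ceil((hi[0] - lo[0]) / pitch)))
        ny = max(2, int(np.ceil((hi[1] - lo[1]) / pitch)))
        gx = lo[0] + (np.arange(nx) + 0.5) * pitch
        gy = lo[1] + (np.arange(ny) + 0.5) * pitch
        covered = np.zeros((nx, ny), dtype=bool)
        for (px, py), rad in zip(pts, r):
            ix = np.nonzero(np.abs(gx - px) <= rad)[0]
            iy = np.nonzero(np.abs(gy - py) <= rad)[0]
            if len(ix) == 0 or len(iy) == 0:
                continue
            dx2 = (gx[ix] - px) ** 2
            dy2 = (gy[iy] - py) ** 2
            disk = dx2[:, None] + dy2[None, :] <= rad ** 2
            covered[np.ix_(ix, iy)] |= disk
        areas.append(covered.sum() * pitch ** 2)
    return tuple(sorted(areas))


def elongation_flatness(triple):
    """Elongation p = small/medium, flatness q = medium/large of a sorted
    ascending size triple; degenerate zero denominators report 0."""
    small, medium, large = triple
    if not (small <= medium <= large):
        raise ValueError("triple must be sorted ascending")
    if large <= 0:
        raise ValueError("undefined shape: largest value is zero")
    p = small / medium if medium > 0 else 0.0
    q = medium / large
    return p, q


def sphericity_from_volume_area(volume: float, area: float) -> float:
    """psi = surface area of the volume-equivalent sphere / actual area."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def vdw_volume(conf: Conformer, pitch: float = DEFAULT_VOXEL_PITCH,
               probe: float = 0.0) -> float:
    """Union volume of (optionally probe-inflated) atomic spheres by voxel
    counting (Angstrom^3)."""
    r = conf.radii + probe
    lo = (conf.coords - r[:, None]).min(axis=0) - pitch
    hi = (conf.coords + r[:, None]).max(axis=0) + pitch
    ns = np.maximum(2, np.ceil((hi - lo) / pitch).astype(int))
    axes = [lo[k] + (np.arange(ns[k]) + 0.5) * pitch for k in range(3)]
    covered = np.zeros(tuple(ns), dtype=bool)
    for center, rad in zip(conf.coords, r):
        idx = [np.nonzero(np.abs(axes[k] - center[k]) <= rad)[0]
               for k in range(3)]
        if any(len(i) == 0 for i in idx):
            continue
        d2 = (((axes[0][idx[0]] - center[0]) ** 2)[:, None, None]
              + ((axes[1][idx[1]] - center[1]) ** 2)[None, :, None]
              + ((axes[2][idx[2]] - center[2]) ** 2)[None, None, :])
        covered[np.ix_(*idx)] |= d2 <= rad ** 2
    return float(covered.sum()) * pitch ** 3


def _sphere_points(n: int) -> np.ndarray:
    # deterministic Fibonacci sphere
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(conf: Conformer, probe: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_SASA_POINTS) -> float:
    """Solvent-accessible surface area by the Shrake-Rupley method
    (Angstrom^2), deterministic via a Fibonacci point sphere."""
    r = conf.radii + probe
    sphere = _sphere_points(n_points)
    total = 0.0
    coords = conf.coords
    for i in range(len(coords)):
        pts = coords[i] + r[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > r[j] ** 2
            if not accessible.any():
                break
        total += 4.0 * np.pi * r[i] ** 2 * accessible.mean()
    return float(total)


def sphericity(conf: Conformer, probe: float = DEFAULT_PROBE_RADIUS,
               volume_kind: str = "probe_inflated") -> float:
    """Sphericity psi of a conformer (see module docstring).

    ``volume_kind`` selects the volume convention: "probe_inflated"
    (default: union of probe-inflated spheres — the volume enclosed by the
    same solvent-accessible surface that SASA measures, so a single sphere
    scores exactly 1 and psi <= 1 throughout) or "vdw" (bare vdW union
    volume; systematically lower and not normalized to 1 at the sphere
    limit, kept for comparison).
    """
    if volume_kind == "vdw":
        vol = vdw_volume(conf)
    elif volume_kind == "probe_inflated":
        vol = vdw_volume(conf, probe=probe)
    else:
        raise ValueError(f"unknown volume_kind {volume_kind!r}")
    return sphericity_from_volume_area(vol, sasa(conf, probe=probe))


@dataclass(frozen=True)
class ShapeDescriptors:
    pmi: tuple           # I1 <= I2 <= I3
    npr1: float
    npr2: float
    shadow: tuple        # S1 <= S2 <= S3
    p_pmi: float
    q_pmi: float
    p_shadow: float
    q_shadow: float
    psi: float
    sa_vol: float
    sasa: float

    FIVE = ("p_shadow", "p_pmi", "q_shadow", "q_pmi", "psi")

    def five_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIVE])


def shape_descriptors(conf: Conformer,
                      probe: float = DEFAULT_PROBE_RADIUS) -> ShapeDescriptors:
    """All shape descriptors of one conformer."""
    pmi, (npr1, npr2) = principal_moments(conf)
    shadow = shadow_areas(conf)
    p_pmi, q_pmi = elongation_flatness(pmi)
    p_sh, q_sh = elongation_flatness(shadow)
    area = sasa(conf, probe=probe)
    return ShapeDescriptors(
        pmi=pmi, npr1=npr1, npr2=npr2, shadow=shadow,
        p_pmi=p_pmi, q_pmi=q_pmi, p_shadow=p_sh, q_shadow=q_sh,
        psi=sphericity_from_volume_area(vdw_volume(conf, probe=probe),
                                        area),
        sa_vol=vdw_volume(conf), sasa=area)


# --------------------------------------------------------------------------
# PCA shape map
# --------------------------------------------------------------------------

@dataclass
class ShapeMap:
    scaler: StandardScaler
    pca: PCA
    pc_min: np.ndarray   # per-PC scaling minimum (from the scaling sets)
    pc_max: np.ndarray
    grid_size: int = GRID_SIZE

    def scores(self, matrix) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        return self.pca.transform(self.scaler.transform(matrix))[:, :2]

    def scaled_scores(self, matrix) -> np.ndarray:
        """PC1/PC2 scores min-max scaled to [0, 1] over the scaling sets;
        out-of-range values are clamped."""
        s = self.scores(matrix)
        span = np.where(self.pc_max > self.pc_min,
                        self.pc_max - self.pc_min, 1.0)
        return np.clip((s - self.pc_min) / span, 0.0, 1.0)


def shape_pca_fit(reference, scaling_sets=None) -> ShapeMap:
    """Fit the five-descriptor PCA shape model.

    ``reference`` is an (n, 5) matrix of descriptors used to standardize
    and fit the PCA; ``scaling_sets`` (default: the reference itself) is an
    iterable of matrices whose pooled PC1/PC2 extrema define the [0, 1]
    display scaling.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2 or reference.shape[0] < 5:
        raise ValueError("need at least 5 reference rows")
    if np.isnan(reference).any():
        raise ValueError("missing values in reference matrix")
    constant = np.nonzero(reference.std(axis=0) == 0)[0]
    if len(constant):
        raise ValueError(f"constant descriptor columns: {constant.tolist()}")
    scaler = StandardScaler().fit(reference)
    pca = PCA(n_components=min(5, reference.shape[1])).fit(
        scaler.transform(reference))
    model = ShapeMap(scaler=scaler, pca=pca,
                     pc_min=np.zeros(2), pc_max=np.ones(2))
    pooled = np.vstack([model.scores(m) for m in
                        (scaling_sets if scaling_sets is not None
                         else [reference])])
    model.pc_min = pooled.min(axis=0)
    model.pc_max = pooled.max(axis=0)
    return model


def shape_map_project(model: ShapeMap, matrix,
                      grid_size: int = None) -> np.ndarray:
    """Project descriptor rows through the model onto an integer frequency
    grid (default 50x50).  Out-of-range scores clamp to edge bins, so the
    grid total always equals the number of rows."""
    g = grid_size or model.grid_size
    grid = np.zeros((g, g), dtype=int)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return grid
    scaled = model.scaled_scores(matrix)
    bins = np.minimum((scaled * g).astype(int), g - 1)
    for i, j in bins:
        grid[i, j] += 1
    return grid


def pmi_triangle(conformers):
    """(npr1, npr2) pairs for a conformer collection — the rod (0,1) /
    disc (0.5,0.5) / sphere (1,1) triangle coordinates."""
    out = []
    for conf in conformers:
        _, npr = principal_moments(conf)
        out.append(npr)
    return out
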