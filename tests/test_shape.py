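"""Shape mathematics: PMI, shadow areas, p/q, sphericity, PCA map."""

import numpy as np
import pytest

from enumol.fixtures import analytic_conformers
from enumol.shape import (Conformer, elongation_flatness, embed_conformer,
                          pmi_triangle, principal_moments, sasa,
                          shadow_areas, shape_descriptors, shape_map_project,
                          shape_pca_fit, sphericity,
                          sphericity_from_volume_area, vdw_volume)


def test_analytic_npr_limits(point_sets):
    _, rod = principal_moments(point_sets["rod"])
    assert rod[0] == pytest.approx(0.0, abs=1e-12)
    assert rod[1] == pytest.approx(1.0, abs=1e-12)
    _, disc = principal_moments(point_sets["disc"])
    assert disc == (pytest.approx(0.5), pytest.approx(0.5))
    _, sphere = principal_moments(point_sets["sphere"])
    assert sphere == (pytest.approx(1.0), pytest.approx(1.0))
    _, ico = principal_moments(point_sets["icosahedron"])
    assert ico == (pytest.approx(1.0), pytest.approx(1.0))


def test_npr_triangle_constraint(point_sets, deck):
    confs = list(point_sets.values())
    confs += [embed_conformer(e.smiles) for e in deck[:4]]
    for npr1, npr2 in pmi_triangle(confs):
        assert npr1 + npr2 >= 1.0 - 1e-9


def test_elongation_flatness_arithmetic():
    assert elongation_flatness((1.0, 2.0, 4.0)) == (0.5, 0.5)
    assert elongation_flatness((3.0, 3.0, 3.0)) == (1.0, 1.0)
    p, q = elongation_flatness((1e-12, 2.0, 2.0))
    assert p == pytest.approx(0.0, abs=1e-9)
    assert q == 1.0
    with pytest.raises(ValueError):
        elongation_flatness((0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        elongation_flatness((3.0, 2.0, 1.0))


def test_sphericity_closed_form():
    assert sphericity_from_volume_area(1.0, 10.0) == pytest.approx(
        np.pi ** (1 / 3) * 6 ** (2 / 3) / 10, abs=1e-9)
    assert sphericity_from_volume_area(1.0, 10.0) == pytest.approx(
        0.4836, abs=1e-4)
    # identity: the sphere's own volume and area give exactly 1
    r = 1.9
    assert sphericity_from_volume_area(
        4 / 3 * np.pi * r ** 3, 4 * np.pi * r ** 2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sphericity_from_volume_area(0.0, 1.0)


def test_single_atom_numeric_sphericity_near_one():
    conf = Conformer.from_points([[0.0, 0.0, 0.0]], radius=1.7)
    # vdW volume vs SASA at probe 0: psi -> 1 up to discretization
    vol = vdw_volume(conf, pitch=0.1)
    area = sasa(conf, probe=0.0)
    assert sphericity_from_volume_area(vol, area) == pytest.approx(1.0,
                                                                   abs=0.02)


def test_sphericity_decreases_with_elongation():
    separations = [0.5, 1.5, 2.5, 3.5]
    psis = [sphericity(Conformer.from_points([[0, 0, 0], [d, 0, 0]]))
            for d in separations]
    assert all(b < a for a, b in zip(psis, psis[1:]))
    # psi <= 1 up to voxel discretization of the volume
    assert all(p <= 1.005 for p in psis)


def test_size_invariance_of_p_q_psi(point_sets):
    """p, q, psi depend only on shape: doubling every length (coordinates,
    radii and the solvent probe) leaves them unchanged."""
    base = point_sets["sphere"]
    doubled = point_sets["sphere_x2"]
    d1 = shape_descriptors(base, probe=1.4)
    d2 = shape_descriptors(doubled, probe=2.8)
    assert d2.p_pmi == pytest.approx(d1.p_pmi, abs=1e-6)
    assert d2.q_pmi == pytest.approx(d1.q_pmi, abs=1e-6)
    assert d2.p_shadow == pytest.approx(d1.p_shadow, rel=0.02)
    assert d2.q_shadow == pytest.approx(d1.q_shadow, rel=0.02)
    assert d2.psi == pytest.approx(d1.psi, rel=0.05)


def test_shadow_single_atom_is_disk():
    conf = Conformer.from_points([[0.0, 0.0, 0.0]], radius=1.7)
    for area in shadow_areas(conf, pitch=0.05):
        assert area == pytest.approx(np.pi * 1.7 ** 2, rel=0.01)


def test_shadow_two_far_atoms():
    conf = Conformer.from_points([[0, 0, 0], [10.0, 0, 0]], radius=1.0)
    s1, s2, s3 = shadow_areas(conf, pitch=0.05)
    assert s1 == pytest.approx(np.pi, rel=0.02)        # disks coincide
    assert s2 == pytest.approx(2 * np.pi, rel=0.02)    # two separate disks
    assert s3 == pytest.approx(2 * np.pi, rel=0.02)


def test_shadow_raster_convergence(deck):
    conf = embed_conformer(next(e for e in deck if e.name == "benzene")
                           .smiles)
    coarse = np.array(shadow_areas(conf, pitch=0.2))
    fine = np.array(shadow_areas(conf, pitch=0.1))
    assert np.all(np.abs(coarse - fine) / fine < 0.01)


def test_embedding_determinism_and_geometry():
    a = embed_conformer("C", seed=11)
    b = embed_conformer("C", seed=11)
    assert np.allclose(a.coords, b.coords)
    # near-tetrahedral H-C-H angles
    c = a.coords - a.coords[0]
    hs = c[1:]
    for i in range(4):
        for j in range(i + 1, 4):
            cos = hs[i] @ hs[j] / (np.linalg.norm(hs[i])
                                   * np.linalg.norm(hs[j]))
            angle = np.degrees(np.arccos(cos))
            assert abs(angle - 109.47) < 3.0


def test_benzene_embeds_planar():
    conf = embed_conformer("c1ccccc1", seed=5)
    ring = conf.coords[:6] - conf.coords[:6].mean(axis=0)
    _, s, _ = np.linalg.svd(ring)
    rms_out_of_plane = s[2] / np.sqrt(6)
    assert rms_out_of_plane < 0.05


def test_adamantane_is_sphere_like():
    conf = embed_conformer("C1C2CC3CC1CC(C2)C3")
    _, (npr1, npr2) = principal_moments(conf)
    assert npr1 > 0.9 and npr2 > 0.9


def test_pca_model_and_grid():
    rng = np.random.default_rng(0)
    ref = rng.uniform(0.1, 1.0, size=(40, 5))
    model = shape_pca_fit(ref)
    scaled = model.scaled_scores(ref)
    assert scaled.min() >= 0.0 and scaled.max() <= 1.0
    # PCA contract: explained variance non-increasing
    ev = model.pca.explained_variance_
    assert ev[0] >= ev[1]
    # duplicated rows project identically
    dup = np.vstack([ref[0], ref[0]])
    s = model.scores(dup)
    assert np.allclose(s[0], s[1])
    grid = shape_map_project(model, ref)
    assert grid.shape == (50, 50)
    assert grid.sum() == len(ref)
    # far out-of-range points clamp to edge bins, conserving the total
    wild = np.vstack([ref[0] + 100.0, ref[0] - 100.0])
    assert shape_map_project(model, wild).sum() == 2
    assert shape_map_project(model, np.empty((0, 5))).sum() == 0


def test_pca_rejects_constant_columns():
    bad = np.ones((10, 5))
    bad[:, :4] = np.random.default_rng(1).normal(size=(10, 4))
    with pytest.raises(ValueError):
        shape_pca_fit(bad)


def test_grid_single_point_at_scaling_minimum():
    rng = np.random.default_rng(2)
    ref = rng.normal(size=(30, 5))
    model = shape_pca_fit(ref)
    scores = model.scores(ref)
    corner = ref[np.argmin(scores[:, 0])]
    # a point at the PC minimum lands in row 0 of the grid
    grid = shape_map_project(model, corner[None, :])
    assert grid[0].sum() == 1 or grid[:, 0].sum() == 1
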