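"""Generator: swept surfaces, tessellation, voxelization."""

import numpy as np
import pytest
import trimesh

from boxtess.synthetic import (CarapaceSpec, SurfacePartition,
                               generate_surface, tessellate, voxelize,
                               synthesize_carapace, thickness_field,
                               face_curvature_proxy)
from boxtess.morphometrics import scute_volume, measure_specimen
from boxtess import io as btio


@pytest.mark.parametrize("gcls", ["elliptic", "triangular", "tetragonal"])
def test_surface_closed_and_sized(gcls):
    spec = CarapaceSpec(geometry_class=gcls, length_mm=50, height_mm=25,
                        width_mm=22)
    mesh = generate_surface(spec)
    assert mesh.is_watertight
    assert mesh.euler_number == 2
    assert np.allclose(mesh.extents, [50, 22, 25], rtol=0.02)


def test_elliptic_full_rounding_matches_ellipsoid_area():
    # corner_rounding = 1 with quadratic taper is an ellipsoid; oracle =
    # dense numerical quadrature of the ellipsoid surface area
    a, b, c = 30.0, 10.0, 12.5  # semi-axes: L/2, W/2, H/2
    spec = CarapaceSpec(geometry_class="elliptic", length_mm=2 * a,
                        width_mm=2 * b, height_mm=2 * c,
                        corner_rounding=1.0, taper_power=2.0)
    mesh = generate_surface(spec, n_theta=192, n_sweep=160)

    # quadrature over the parametric ellipsoid
    u = np.linspace(0, np.pi, 400)
    v = np.linspace(0, 2 * np.pi, 800)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    su, cu, sv, cv = np.sin(uu), np.cos(uu), np.sin(vv), np.cos(vv)
    E = np.sqrt((b * c * su ** 2 * cv) ** 2 + (a * c * su ** 2 * sv) ** 2
                + (a * b * su * cu) ** 2)
    analytic = float(np.trapezoid(np.trapezoid(E, v, axis=1), u))
    assert mesh.area == pytest.approx(analytic, rel=0.02)


def test_sharp_tetragonal_prism_approaches_box_area():
    L, H, W = 40.0, 20.0, 18.0
    spec = CarapaceSpec(geometry_class="tetragonal", length_mm=L,
                        height_mm=H, width_mm=W, corner_rounding=0.02,
                        head_rounding=0.02, taper_power=None)
    mesh = generate_surface(spec, n_theta=256)
    box = 2 * (L * H + L * W + H * W)
    assert mesh.area == pytest.approx(box, rel=0.03)


def test_degenerate_spec_rejected():
    with pytest.raises(ValueError):
        CarapaceSpec(length_mm=0.0)
    with pytest.raises(ValueError):
        CarapaceSpec(corner_rounding=0.0)
    with pytest.raises(ValueError):
        CarapaceSpec(n_scutes=120, n_openings=12)


def test_two_region_sphere_partition():
    mesh = trimesh.creation.icosphere(subdivisions=3)
    part = tessellate(mesh, n_scutes=2, n_openings=0, seed=0)
    assert set(part.scute_ids) == {1, 2}
    adj = mesh.face_adjacency
    labs = part.face_label
    touching = {(int(min(a, b)), int(max(a, b)))
                for a, b in zip(labs[adj[:, 0]], labs[adj[:, 1]]) if a != b}
    assert touching == {(1, 2)}  # each region has exactly one neighbor


def test_partition_conserves_area_and_is_deterministic():
    mesh = trimesh.creation.icosphere(subdivisions=4)
    p1 = tessellate(mesh, n_scutes=60, n_openings=0, seed=5)
    p2 = tessellate(mesh, n_scutes=60, n_openings=0, seed=5)
    assert np.array_equal(p1.face_label, p2.face_label)
    region_area = sum(mesh.area_faces[p1.face_label == sid].sum()
                      for sid in p1.scute_ids)
    assert region_area == pytest.approx(mesh.area, rel=1e-9)
    with pytest.raises(ValueError):
        tessellate(mesh, n_scutes=len(mesh.faces) + 1, n_openings=0, seed=0)


def test_sphere_tessellation_neighbor_counts_follow_euler():
    # trivalent tessellation of a genus-0 surface: mean degree 6 - 12/n
    mesh = trimesh.creation.icosphere(subdivisions=5)
    n = 400
    part = tessellate(mesh, n_scutes=n, n_openings=0, seed=11,
                      lloyd_iters=8)
    adj = mesh.face_adjacency
    labs = part.face_label
    pairs = {(int(min(a, b)), int(max(a, b)))
             for a, b in zip(labs[adj[:, 0]], labs[adj[:, 1]]) if a != b}
    mean_deg = 2 * len(pairs) / n
    assert mean_deg == pytest.approx(6 - 12 / n, abs=0.35)
    assert mean_deg < 6  # Euler bound


def test_voxelized_shell_volume_matches_analytic(sphere_shell_volume):
    v = scute_volume(sphere_shell_volume, 1)
    analytic = 4 / 3 * np.pi * (10.0 ** 3 - 9.0 ** 3)
    assert v == pytest.approx(analytic, rel=0.05)


def test_voxelize_rejects_coarse_resolution(small_carapace, small_spec):
    part, _ = small_carapace
    from dataclasses import replace
    coarse = replace(small_spec, voxel_mm=small_spec.base_thickness_mm)
    with pytest.raises(ValueError, match="coarse"):
        voxelize(part, coarse)


def test_uniform_thickness_without_edge_factor():
    # constant-curvature geometry (sphere): every scute sees the same
    # wrap, so edge_thickness_factor = 1 must give uniform thickness
    spec = CarapaceSpec(length_mm=24, height_mm=23.9, width_mm=23.8,
                        geometry_class="elliptic", corner_rounding=1.0,
                        head_rounding=1.0, n_scutes=120, n_openings=0,
                        seed=3, edge_thickness_factor=1.0,
                        base_thickness_mm=0.6, voxel_mm=0.2)
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=12.0)
    part = tessellate(mesh, spec.n_scutes, 0, seed=3)
    vol = voxelize(part, spec)
    rec, _ = measure_specimen(vol, "t")
    q10, q90 = rec.thickness.quantile([0.1, 0.9])
    # uniform within voxelization tolerance
    assert q90 - q10 < 2.0 * spec.voxel_mm


def test_edge_thickening_ratio_recovers_factor_two():
    spec = CarapaceSpec(length_mm=36, height_mm=18, width_mm=16,
                        n_scutes=150, n_openings=0, seed=3,
                        edge_thickness_factor=2.0, base_thickness_mm=1.2,
                        voxel_mm=0.18)
    mesh = generate_surface(spec, n_theta=128, n_sweep=96)
    part = tessellate(mesh, spec.n_scutes, 0, seed=3)
    tfield = thickness_field(part, spec)  # curvature rule, no planted types
    vol = voxelize(part, spec, face_thickness=tfield)
    rec, _ = measure_specimen(vol, "t")
    # oracle: the generator's own thickness field says which scutes are
    # thickened
    area = mesh.area_faces
    planted = {}
    for sid in part.scute_ids:
        sel = part.face_label == sid
        planted[int(sid)] = np.average(tfield[sel], weights=area[sel])
    thick = rec.scute_id.map(planted)
    is_edge = thick > 1.5 * spec.base_thickness_mm
    ratio = (rec.thickness[is_edge].median()
             / rec.thickness[~is_edge].median())
    assert ratio == pytest.approx(2.0, rel=0.15)


def test_synthesis_determinism_and_roundtrip(small_spec, small_carapace,
                                             tmp_path):
    part, vol = small_carapace
    part2, vol2 = synthesize_carapace(small_spec)
    assert np.array_equal(vol.labels, vol2.labels)
    assert np.array_equal(part.face_label, part2.face_label)
    # label volume round-trips bit-exactly through the TIFF writer
    p = tmp_path / "labels.tif"
    btio.write_label_volume(p, vol)
    back = btio.read_label_volume(p)
    assert np.array_equal(back.labels, vol.labels)
    assert back.voxel_mm == pytest.approx(vol.voxel_mm)
    assert back.origin_mm == pytest.approx(vol.origin_mm)


def test_planted_types_cover_all_scutes(small_carapace):
    part, _ = small_carapace
    assert set(part.planted_type) == {int(s) for s in part.scute_ids}
    assert set(part.planted_type.values()) <= {1, 2, 3, 4, 5}


def test_neighbor_distribution_mode_six(measured_small):
    records, _ = measured_small
    counts = records.n_neighbors.value_counts()
    assert counts.idxmax() == 6
    assert records.n_neighbors.mean() < 6
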