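import numpy as np
import pytest
import trimesh

from boxtess.synthetic import CarapaceSpec, synthesize_carapace


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast-to-voxelize carapace for unit tests."""
    return CarapaceSpec(geometry_class="tetragonal", length_mm=30.0,
                        height_mm=15.0, width_mm=13.5, n_scutes=140,
                        n_openings=4, base_thickness_mm=0.5,
                        voxel_mm=0.21, seed=7)


@pytest.fixture(scope="session")
def small_carapace(small_spec):
    partition, volume = synthesize_carapace(small_spec)
    return partition, volume


@pytest.fixture(scope="session")
def measured_small(small_spec, small_carapace):
    from boxtess.morphometrics import measure_specimen

    _, volume = small_carapace
    records, summary = measure_specimen(
        volume, specimen_id="unit", geometry_class="tetragonal",
        axes_hint=np.array([0.0, 0.0, 1.0]))
    return records, summary


@pytest.fixture()
def sphere_shell_volume():
    """Single-scute spherical shell: radius 10 mm, thickness 1 mm."""
    from boxtess.synthetic import SurfacePartition, voxelize

    mesh = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    part = SurfacePartition(
        mesh=mesh, face_label=np.ones(len(mesh.faces), dtype=np.int64),
        generator_points={1: np.array([10.0, 0.0, 0.0])})
    spec = CarapaceSpec(length_mm=25, height_mm=20, width_mm=20,
                        base_thickness_mm=1.0, voxel_mm=0.2,
                        n_openings=0)
    vol = voxelize(part, spec,
                   face_thickness=np.full(len(mesh.faces), 1.0))
    return vol
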