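"""Phantom geometry, modality imaging, boundary helpers, WSS synthesis."""

import math

import numpy as np
import pytest

from aneumorph import (AneurysmSpec, ConfigurationError, ImageVolume,
                       InletSpec, ModalityProfile, PhantomGeometry, Region,
                       WSSSynthesisSpec, build_phantom_mesh, compute_osi,
                       default_modality_profiles, default_waveform,
                       inlet_mean_velocity, morpho_report, peak_reynolds,
                       synthesize_wss, time_average_wss, voxelize)
from aneumorph.hemodynamics import compute_awssg
from aneumorph.phantom import aneurysm_subregions


class TestGroundTruth:
    def test_closed_form_values(self, cap_phantom):
        _, _, truth = cap_phantom
        b = math.sqrt(3.0 ** 2 - 1.5 ** 2)
        assert truth.size == pytest.approx(3.0 + b, rel=1e-12)      # 5.598
        assert truth.NA == pytest.approx(math.pi * 1.5 ** 2, rel=1e-12)
        assert truth.AR == pytest.approx((3.0 + b) / 3.0, rel=1e-12)  # 1.866
        assert truth.PVD == pytest.approx(4.0)
        assert truth.SR == pytest.approx((3.0 + b) / 4.0, rel=1e-12)
        assert truth.AA == pytest.approx(90.0)

    def test_dense_sampling_oracle(self, cap_phantom, cap_geometry):
        """Closed forms agree with brute-force measures of a fine isosurface."""
        spec, _, truth = cap_phantom
        import trimesh
        from skimage import measure as skmeasure

        geom = cap_geometry
        h = 0.08
        lo = np.array([-4.5, -4.5, 1.0])
        hi = np.array([4.5, 4.5, 9.0])
        shape = np.ceil((hi - lo) / h).astype(int) + 1
        axes = [lo[i] + h * np.arange(shape[i]) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        sdf = geom.signed_distance(grid.reshape(-1, 3)).reshape(grid.shape[:3])
        v, f, _, _ = skmeasure.marching_cubes(sdf, level=-1e-6, spacing=(h, h, h))
        dense = trimesh.Trimesh(v + lo, f, process=True)
        plane_z = geom.anchor[2]
        above = dense.vertices[dense.vertices[:, 2] > plane_z + 1e-6]
        size_oracle = above[:, 2].max() - plane_z
        assert size_oracle == pytest.approx(truth.size, rel=0.005)
        # neck radius sampled on the cylindrical collar below the plane
        vv = dense.vertices
        ring = vv[(vv[:, 2] > plane_z - 0.35) & (vv[:, 2] < plane_z - 0.15)]
        na_oracle = math.pi * np.linalg.norm(ring[:, :2], axis=1).mean() ** 2
        assert na_oracle == pytest.approx(truth.NA, rel=0.01)

    def test_cylinder_lateral_area(self):
        spec = AneurysmSpec(sac_radius=0.0, parent_radius=2.0,
                            parent_length=20.0, mesh_edge_length=0.2)
        lmesh, truth = build_phantom_mesh(spec)
        assert truth.undefined
        mesh = lmesh.mesh
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.99
        area = mesh.area_faces[lateral].sum()
        assert area == pytest.approx(2 * math.pi * 2.0 * 20.0, rel=0.01)

    def test_degenerate_sac_flagged(self):
        lmesh, truth = build_phantom_mesh(AneurysmSpec(sac_radius=0.0,
                                                       mesh_edge_length=0.3))
        assert truth.undefined
        assert not lmesh.faces_in(Region.ANEURYSM).any()
        assert math.isnan(morpho_report(lmesh).size)

    def test_mesh_is_watertight_and_oriented(self, cap_phantom):
        _, lmesh, _ = cap_phantom
        assert lmesh.mesh.is_watertight
        assert lmesh.mesh.is_winding_consistent
        assert lmesh.mesh.volume > 0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            AneurysmSpec(neck_radius=4.0, sac_radius=3.0)
        with pytest.raises(ConfigurationError):
            AneurysmSpec(mesh_edge_length=0.0)
        with pytest.raises(ConfigurationError):
            AneurysmSpec(parent_curvature=0.5, parent_length=24.0)


class _Sphere:
    """Implicit sphere for voxelization tests."""

    def __init__(self, radius):
        self.radius = radius
        self.bounds = np.array([[-radius] * 3, [radius] * 3], float)

    def signed_distance(self, pts):
        return np.linalg.norm(np.asarray(pts, float), axis=1) - self.radius


class TestVoxelize:
    def test_sphere_volume(self):
        profile = ModalityProfile("test", (0.25, 0.25, 0.25), 0.0, 0.0)
        vol = voxelize(_Sphere(5.0), profile)
        count = np.count_nonzero(vol.data >= 0.5)
        measured = count * np.prod(vol.spacing)
        assert measured == pytest.approx(4.0 / 3.0 * math.pi * 125.0, rel=0.02)

    def test_midpoint_threshold_reproduces_occupancy(self):
        profile = ModalityProfile("test", (0.3, 0.3, 0.3), 0.0, 0.0)
        sphere = _Sphere(4.0)
        vol = voxelize(sphere, profile)
        shape = vol.shape
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        centers = vol.index_to_world(idx)
        inside = sphere.signed_distance(centers).reshape(shape) <= 0
        assert np.array_equal(vol.data >= 0.5, inside)

    def test_determinism(self, cap_geometry):
        profile = default_modality_profiles(rng_seed=42)["CTA_like"]
        v1 = voxelize(cap_geometry, profile)
        v2 = voxelize(cap_geometry, profile)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(v1.origin, v2.origin)

    def test_coarse_spacing_warns_in_provenance(self, cap_geometry):
        profile = ModalityProfile("coarse", (2.0, 2.0, 2.0), 0.0, 0.0)
        vol = voxelize(cap_geometry, profile)
        assert any("spacing" in w for w in vol.provenance.get("warnings", []))

    def test_nifti_mha_roundtrip(self, tmp_path):
        profile = ModalityProfile("test", (0.5, 0.5, 0.5), 0.0, 0.0)
        vol = voxelize(_Sphere(3.0), profile)
        for name, loader in [("v.nii.gz", ImageVolume.from_nifti),
                             ("v.mha", ImageVolume.from_mha)]:
            path = tmp_path / name
            (vol.to_nifti if name.endswith("gz") else vol.to_mha)(path)
            back = loader(path)
            assert np.allclose(back.data, vol.data, atol=1e-6)
            assert np.allclose(back.spacing, vol.spacing)
            assert np.allclose(back.origin, vol.origin, atol=1e-5)


class TestInletHelpers:
    def test_constant_flow_unit_velocity(self):
        import aneumorph.phantom as ph

        wf = ph.Waveform(times=np.array([0.0, 0.4, 0.8]),
                         flow_rates=np.array([math.pi] * 3), period=0.8)
        v = inlet_mean_velocity(wf, InletSpec(diameter=2.0), 0.3)
        assert v == pytest.approx(1.0)

    def test_velocity_scaling_with_diameter(self):
        wf = default_waveform()
        v1 = inlet_mean_velocity(wf, InletSpec(diameter=2.0), 0.1)
        v2 = inlet_mean_velocity(wf, InletSpec(diameter=4.0), 0.1)
        assert v1 == pytest.approx(4.0 * v2)

    def test_peak_reynolds_in_physiological_range(self):
        re = peak_reynolds(default_waveform(), InletSpec(diameter=4.0))
        assert 500.0 <= re <= 750.0

    def test_invalid_inlet(self):
        with pytest.raises(ConfigurationError):
            InletSpec(diameter=-1.0)
        with pytest.raises(ConfigurationError):
            InletSpec(diameter=4.0, outflow_split=(0.7, 0.4))

    def test_waveform_periodicity_enforced(self):
        import aneumorph.phantom as ph

        with pytest.raises(ConfigurationError):
            ph.Waveform(times=np.array([0.0, 0.4, 0.8]),
                        flow_rates=np.array([1.0, 2.0, 3.0]), period=0.8)

    def test_waveform_csv_roundtrip(self, tmp_path):
        import aneumorph.phantom as ph

        wf = default_waveform()
        wf.save_csv(tmp_path / "wf.csv")
        back = ph.Waveform.load_csv(tmp_path / "wf.csv")
        assert np.allclose(back.times, wf.times)
        assert np.allclose(back.flow_rates, wf.flow_rates)


@pytest.fixture(scope="module")
def synth_setup():
    lmesh, _ = build_phantom_mesh(AneurysmSpec(mesh_edge_length=0.3))
    return lmesh, default_waveform()


class TestWSSSynthesis:
    def test_exact_periodicity(self, synth_setup):
        lmesh, wf = synth_setup
        field = synthesize_wss(lmesh, wf, WSSSynthesisSpec(rng_seed=1))
        assert np.array_equal(field.vectors[0], field.vectors[-1])

    def test_determinism(self, synth_setup):
        lmesh, wf = synth_setup
        f1 = synthesize_wss(lmesh, wf, WSSSynthesisSpec(rng_seed=5))
        f2 = synthesize_wss(lmesh, wf, WSSSynthesisSpec(rng_seed=5))
        assert np.array_equal(f1.vectors, f2.vectors)

    def test_steady_unidirectional_field_has_zero_osi(self, synth_setup):
        import aneumorph.phantom as ph

        lmesh, _ = synth_setup
        t = np.linspace(0, 0.8, 33)
        wf = ph.Waveform(times=t, flow_rates=np.full(33, 4000.0), period=0.8)
        field = synthesize_wss(lmesh, wf,
                               WSSSynthesisSpec(body_oscillation_fraction=0.0,
                                                rng_seed=2))
        assert np.all(compute_osi(field) < 1e-12)

    def test_spatial_pattern(self, synth_setup):
        """Low AWSS on the dome, high OSI on the body, high AWSSG at the neck."""
        lmesh, wf = synth_setup
        field = synthesize_wss(lmesh, wf, WSSSynthesisSpec(rng_seed=3))
        awss = time_average_wss(field)
        osi = compute_osi(field)
        awssg = compute_awssg(field)
        dome, body = aneurysm_subregions(lmesh)
        parent = lmesh.vertices_in(Region.PARENT_ROI)
        band = lmesh.vertices_in(Region.NECK_BAND)
        assert awss[dome].mean() < awss[parent].mean()
        assert osi[body].mean() > osi[parent].mean()
        assert awssg[band].mean() > awssg[dome].mean()

    def test_too_few_timesteps_rejected(self):
        with pytest.raises(ConfigurationError):
            WSSSynthesisSpec(n_timesteps=4)

    def test_field_io_roundtrip(self, synth_setup, tmp_path):
        from aneumorph import WSSField

        lmesh, wf = synth_setup
        field = synthesize_wss(lmesh, wf, WSSSynthesisSpec(rng_seed=1,
                                                           n_timesteps=8))
        field.save(tmp_path / "wss")
        back = WSSField.load(tmp_path / "wss", mesh_ref=lmesh)
        assert np.allclose(back.vectors, field.vectors, atol=1e-6)
        assert back.period == field.period
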