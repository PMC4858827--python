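"""Cycle statistics (AWSS, OSI), surface gradients (AWSSG), regional stats."""

import math

import numpy as np
import pytest
import trimesh

from aneumorph import (HemoConfig, LabeledSurfaceMesh, Region, WSSField,
                       compute_awssg, compute_osi, oscillatory_shear_index,
                       regional_statistics, surface_gradient,
                       time_average_wss)
from aneumorph._meshutil import vertex_areas, weighted_percentile

from conftest import interior_vertices, make_flat_patch

T = 0.8


def make_field(mesh_or_n, fn, n_times=33):
    """WSSField with per-vertex vectors fn(t, xyz) sampled over one cycle."""
    times = np.linspace(0.0, T, n_times)
    if isinstance(mesh_or_n, int):
        verts = np.zeros((mesh_or_n, 3))
        mesh_ref = None
    else:
        verts = mesh_or_n.mesh.vertices if isinstance(mesh_or_n, LabeledSurfaceMesh) \
            else mesh_or_n.vertices
        mesh_ref = mesh_or_n if isinstance(mesh_or_n, LabeledSurfaceMesh) else None
    vectors = np.stack([fn(t, verts) for t in times])
    return WSSField(mesh_ref=mesh_ref, times=times, vectors=vectors, period=T,
                    t_peak_systole=times[n_times // 2], t_end_diastole=times[-1])


class TestAWSS:
    def test_constant_vector(self):
        field = make_field(4, lambda t, v: np.tile([2.0, 0.0, 0.0], (len(v), 1)))
        assert np.allclose(time_average_wss(field), 2.0)

    def test_zero_mean_sinusoid(self):
        field = make_field(3, lambda t, v: np.tile(
            [math.sin(2 * math.pi * t / T), 0.0, 0.0], (len(v), 1)))
        assert np.allclose(time_average_wss(field), 0.0, atol=1e-12)

    def test_offset_sinusoid_against_quadrature_oracle(self):
        from scipy.integrate import quad

        field = make_field(2, lambda t, v: np.tile(
            [1.0 + math.sin(2 * math.pi * t / T), 0.0, 0.0], (len(v), 1)))
        oracle, _ = quad(lambda t: 1.0 + math.sin(2 * math.pi * t / T), 0.0, T)
        oracle /= T
        assert time_average_wss(field)[0] == pytest.approx(oracle, abs=1e-3)
        assert oracle == pytest.approx(1.0, abs=1e-9)

    def test_awss_not_exceeding_mean_magnitude(self):
        rng = np.random.default_rng(5)
        coef = rng.normal(size=(3, 8, 3))

        def fn(t, v):
            th = 2 * math.pi * t / T
            return (coef[0] + coef[1] * math.sin(th) + coef[2] * math.cos(th))

        field = make_field(8, fn)
        awss = time_average_wss(field)
        _, mean_mag = __import__("aneumorph.hemodynamics", fromlist=["x"])._cycle_integrals(field)
        assert np.all(awss <= mean_mag + 1e-12)


class TestOSI:
    def test_fixed_direction_zero(self):
        field = make_field(2, lambda t, v: np.tile(
            [1.0 + 0.5 * math.sin(2 * math.pi * t / T), 0.0, 0.0], (len(v), 1)))
        assert np.allclose(compute_osi(field), 0.0, atol=1e-12)

    def test_square_wave_reversal_half(self):
        times = np.linspace(0.0, T, 33)
        vec = np.where((times % T) < T / 2, 1.0, -1.0)[:, None, None] \
            * np.array([1.0, 0.0, 0.0])
        vec[-1] = vec[0]
        assert oscillatory_shear_index(times, vec, T)[0] == pytest.approx(0.5)

    def test_partial_reversal_against_quadrature_oracle(self):
        from scipy.integrate import quad

        def wss_x(t):
            return 1.0 + 2.0 * math.sin(2 * math.pi * t / T)

        num = abs(quad(wss_x, 0, T)[0]) / T
        den = quad(lambda t: abs(wss_x(t)), 0, T, limit=200)[0] / T
        oracle = 0.5 * (1.0 - num / den)
        assert oracle == pytest.approx(0.152, abs=5e-4)

        field = make_field(2, lambda t, v: np.tile([wss_x(t), 0.0, 0.0],
                                                   (len(v), 1)), n_times=513)
        assert compute_osi(field)[0] == pytest.approx(oracle, abs=1e-4)
        field32 = make_field(2, lambda t, v: np.tile([wss_x(t), 0.0, 0.0],
                                                     (len(v), 1)), n_times=33)
        assert compute_osi(field32)[0] == pytest.approx(oracle, abs=5e-3)

    def test_zero_field_osi_zero(self):
        field = make_field(3, lambda t, v: np.zeros((len(v), 3)))
        assert np.allclose(compute_osi(field), 0.0)

    def test_bounds_on_random_fields(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            coef = rng.normal(size=(5, 6, 3))

            def fn(t, v):
                th = 2 * math.pi * t / T
                return sum(coef[i] * math.sin((i + 1) * th + i) for i in range(4)) \
                    + coef[4]

            osi = compute_osi(make_field(6, fn))
            assert np.all(osi >= 0.0) and np.all(osi <= 0.5)

    def test_quadrature_convergence(self):
        def fn(t, v):
            th = 2 * math.pi * t / T
            base = np.array([1.0 + 0.5 * math.sin(th), 0.4 * math.cos(th), 0.0])
            return np.tile(base, (len(v), 1))

        coarse = compute_osi(make_field(4, fn, n_times=33))[0]
        fine = compute_osi(make_field(4, fn, n_times=65))[0]
        assert abs(fine - coarse) / max(fine, 1e-12) < 0.005
        a_coarse = time_average_wss(make_field(4, fn, n_times=33))[0]
        a_fine = time_average_wss(make_field(4, fn, n_times=65))[0]
        assert abs(a_fine - a_coarse) / a_fine < 0.005


class TestSurfaceGradient:
    def test_linear_field_reproduced(self, flat_patch):
        g = surface_gradient(flat_patch, 3.0 * flat_patch.vertices[:, 0])
        interior = interior_vertices(flat_patch)
        assert np.allclose(g[interior], [3.0, 0.0, 0.0], atol=1e-10)

    def test_constant_field_zero_gradient(self, flat_patch):
        g = surface_gradient(flat_patch, np.full(len(flat_patch.vertices), 7.0))
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_quadratic_field_refinement_convergence(self):
        # jittered grids: on the symmetric grid the P1 vertex gradient of x²
        # is superconvergent (exact), so perturb nodes to expose the error
        errs = []
        for n in (16, 32):
            patch = make_flat_patch(n=n)
            rng = np.random.default_rng(1)
            cell = 10.0 / n
            interior = interior_vertices(patch)
            jitter = rng.uniform(-0.25 * cell, 0.25 * cell, (len(patch.vertices), 2))
            verts = patch.vertices.copy()
            verts[interior, :2] += jitter[interior]
            patch = trimesh.Trimesh(verts, patch.faces, process=False)
            g = surface_gradient(patch, patch.vertices[:, 0] ** 2)
            exact = np.column_stack([2 * patch.vertices[interior, 0],
                                     np.zeros(interior.sum()),
                                     np.zeros(interior.sum())])
            errs.append(np.abs(g[interior] - exact).mean())
        assert errs[1] < 0.7 * errs[0]

    def test_gradient_tangential_on_sphere(self):
        sphere = trimesh.creation.icosphere(3, 5.0)
        g = surface_gradient(sphere, sphere.vertices[:, 2])
        normal_comp = np.einsum("ij,ij->i", g, sphere.vertex_normals)
        assert np.abs(normal_comp).max() < 0.05 * np.linalg.norm(g, axis=1).max()


class TestAWSSG:
    def test_linear_single_component(self, flat_patch):
        lmesh = LabeledSurfaceMesh(
            flat_patch, np.full(len(flat_patch.faces),
                                LabeledSurfaceMesh.code(Region.ANEURYSM), np.int8))

        def fn(t, v):
            return np.column_stack([2.0 * v[:, 0], np.zeros(len(v)),
                                    np.zeros(len(v))])

        awssg = compute_awssg(make_field(lmesh, fn))
        interior = interior_vertices(flat_patch)
        assert np.allclose(awssg[interior], 2.0, atol=1e-9)

    def test_uniform_field_zero(self, flat_patch):
        lmesh = LabeledSurfaceMesh(
            flat_patch, np.full(len(flat_patch.faces),
                                LabeledSurfaceMesh.code(Region.ANEURYSM), np.int8))
        field = make_field(lmesh, lambda t, v: np.tile(
            [math.sin(2 * math.pi * t / T) + 2, 1.0, 0.5], (len(v), 1)))
        assert np.allclose(compute_awssg(field), 0.0, atol=1e-12)

    def test_two_linear_components_closed_form(self, flat_patch):
        a, b = 1.5, 2.5
        lmesh = LabeledSurfaceMesh(
            flat_patch, np.full(len(flat_patch.faces),
                                LabeledSurfaceMesh.code(Region.ANEURYSM), np.int8))

        def fn(t, v):
            return np.column_stack([a * v[:, 0], b * v[:, 1], np.zeros(len(v))])

        awssg = compute_awssg(make_field(lmesh, fn))
        interior = interior_vertices(flat_patch)
        assert np.allclose(awssg[interior], math.hypot(a, b), atol=1e-9)


def two_region_patch():
    """Flat patch split into aneurysm (x<0) and parent (x>=0) halves."""
    patch = make_flat_patch(n=20, extent=10.0)
    labels = np.where(patch.triangles_center[:, 0] < 0,
                      LabeledSurfaceMesh.code(Region.ANEURYSM),
                      LabeledSurfaceMesh.code(Region.PARENT_ROI)).astype(np.int8)
    return LabeledSurfaceMesh(patch, labels)


class TestRegionalStatistics:
    def test_uniform_field(self):
        lmesh = two_region_patch()
        field = make_field(lmesh, lambda t, v: np.tile([1.0, 0.0, 0.0],
                                                       (len(v), 1)))
        rep = regional_statistics(field)
        assert rep.MWSS_A == pytest.approx(1.0)
        assert rep.WSS90_A == pytest.approx(1.0)
        assert rep.LWSS_A == 0.0
        assert rep.AWSS_A == pytest.approx(1.0)
        assert rep.OSI_A == 0.0

    def test_half_area_low_wss(self):
        """Exactly half the aneurysm area below 0.4 Pa → LWSS_A = 0.5."""
        lmesh = two_region_patch()
        verts = lmesh.mesh.vertices

        def fn(t, v):
            mag = np.where(v[:, 1] < 0, 0.2, 1.0)
            return np.column_stack([mag, np.zeros(len(v)), np.zeros(len(v))])

        rep = regional_statistics(make_field(lmesh, fn))
        assert rep.LWSS_A == pytest.approx(0.5, abs=0.03)

    def test_weighted_percentile_against_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(5, 60)
            values = rng.uniform(0, 10, n)
            weights = rng.uniform(0.1, 2.0, n)
            q = float(rng.uniform(5, 95))
            got = weighted_percentile(values, weights, q)
            # oracle: smallest value whose cumulative weight fraction >= q
            order = np.argsort(values)
            v, w = values[order], weights[order]
            cw = np.cumsum(w) / w.sum()
            idx = int(np.searchsorted(cw, q / 100.0))
            idx = min(idx, n - 1)
            lo = v[max(idx - 1, 0)]
            hi = v[min(idx + 1, n - 1)]
            assert lo - 1e-12 <= got <= hi + 1e-12

    def test_wss90_le_mwss_on_random_fields(self):
        lmesh = two_region_patch()
        rng = np.random.default_rng(9)
        for seed in range(3):
            mags = rng.uniform(0.1, 5.0, len(lmesh.mesh.vertices))

            def fn(t, v):
                s = 1.0 + 0.3 * math.sin(2 * math.pi * t / T)
                return np.column_stack([mags * s, np.zeros(len(v)),
                                        np.zeros(len(v))])

            rep = regional_statistics(make_field(lmesh, fn))
            assert rep.WSS90_A <= rep.MWSS_A + 1e-12
            assert 0 <= rep.HOSI_A <= 1 and 0 <= rep.LWSS_A <= 1

    def test_missing_region_raises(self, flat_patch):
        from aneumorph.errors import AneumorphError

        lmesh = LabeledSurfaceMesh(
            flat_patch, np.full(len(flat_patch.faces),
                                LabeledSurfaceMesh.code(Region.ANEURYSM), np.int8))
        field = make_field(lmesh, lambda t, v: np.ones((len(v), 3)))
        with pytest.raises(AneumorphError, match="parent_roi"):
            regional_statistics(field)

    def test_rigid_invariance_of_report(self):
        lmesh = two_region_patch()

        def fn(t, v):
            s = 1.0 + 0.5 * math.sin(2 * math.pi * t / T)
            return np.column_stack([s * (1 + 0.1 * v[:, 0]),
                                    0.3 * np.cos(2 * math.pi * t / T)
                                    * np.ones(len(v)), np.zeros(len(v))])

        field = make_field(lmesh, fn)
        rep1 = regional_statistics(field)
        T4 = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3], [4, 5, 6])
        moved_mesh = lmesh.mesh.copy()
        moved_mesh.apply_transform(T4)
        moved = LabeledSurfaceMesh(moved_mesh, lmesh.face_region)
        R = T4[:3, :3]
        field2 = WSSField(mesh_ref=moved, times=field.times,
                          vectors=field.vectors @ R.T, period=T,
                          t_peak_systole=field.t_peak_systole,
                          t_end_diastole=field.t_end_diastole)
        rep2 = regional_statistics(field2)
        for name in rep1.PARAMETERS:
            assert getattr(rep2, name) == pytest.approx(
                getattr(rep1, name), rel=1e-6, abs=1e-9), name

    def test_awssg_scales_inversely_with_length(self):
        lmesh = two_region_patch()

        def fn(t, v):
            return np.column_stack([0.5 * v[:, 0], np.zeros(len(v)),
                                    np.zeros(len(v))])

        rep1 = regional_statistics(make_field(lmesh, fn))
        k = 2.0
        scaled_mesh = lmesh.mesh.copy()
        scaled_mesh.apply_scale(k)
        scaled = LabeledSurfaceMesh(scaled_mesh, lmesh.face_region)
        field2 = make_field(scaled, fn)   # same WSS values at scaled positions

        def fn_fixed(t, v):
            return np.column_stack([0.5 * v[:, 0] / k, np.zeros(len(v)),
                                    np.zeros(len(v))])

        rep2 = regional_statistics(make_field(scaled, fn_fixed))
        assert rep2.AWSSG_A == pytest.approx(rep1.AWSSG_A / k, rel=1e-6)

    def test_vertex_areas_sum_to_surface_area(self, flat_patch):
        assert vertex_areas(flat_patch).sum() == pytest.approx(flat_patch.area)
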