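"""Shared fixtures: phantoms, flat patches, and simple labeled meshes."""

import math

import numpy as np
import pytest
import trimesh

from aneumorph import (AneurysmSpec, LabeledSurfaceMesh, PhantomGeometry,
                       Region, build_phantom_mesh, morpho_report)


@pytest.fixture(scope="session")
def cap_phantom():
    """Sphere-cap phantom (R=3, r_n=1.5, parent radius 2) at 0.2 mm edge."""
    spec = AneurysmSpec(sac_radius=3.0, neck_radius=1.5, parent_radius=2.0,
                        mesh_edge_length=0.2)
    lmesh, truth = build_phantom_mesh(spec)
    return spec, lmesh, truth


@pytest.fixture(scope="session")
def cap_phantom_report(cap_phantom):
    _, lmesh, _ = cap_phantom
    return morpho_report(lmesh)


@pytest.fixture(scope="session")
def cap_geometry(cap_phantom):
    spec, _, _ = cap_phantom
    return PhantomGeometry(spec)


def make_flat_patch(n: int = 20, extent: float = 10.0) -> trimesh.Trimesh:
    """Flat triangulated square patch in the z=0 plane, (n+1)² vertices."""
    xs = np.linspace(-extent / 2, extent / 2, n + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def interior_vertices(mesh: trimesh.Trimesh) -> np.ndarray:
    """Boolean mask of vertices not on the boundary of an open mesh."""
    import collections

    edge_count = collections.Counter(map(tuple, mesh.edges_sorted))
    boundary = {v for e, c in edge_count.items() if c == 1 for v in e}
    mask = np.ones(len(mesh.vertices), dtype=bool)
    mask[list(boundary)] = False
    return mask


def hemisphere_mesh(radius: float = 3.0) -> LabeledSurfaceMesh:
    """Icosphere with the upper hemisphere labeled aneurysm, equator as neck."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    labels = np.where(sphere.triangles_center[:, 2] > 0,
                      LabeledSurfaceMesh.code(Region.ANEURYSM),
                      LabeledSurfaceMesh.code(Region.PARENT_ROI)).astype(np.int8)
    psi = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    curve = radius * np.column_stack([np.cos(psi), np.sin(psi), np.zeros_like(psi)])
    return LabeledSurfaceMesh(sphere, labels, neck_curve=curve)


@pytest.fixture()
def flat_patch():
    return make_flat_patch()
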