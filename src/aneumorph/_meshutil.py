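"""Low-level mesh helpers shared across modules.

Closest-point queries are done with a KD-tree over triangle centroids plus
exact point-to-triangle projection on a candidate set, so no spatial-index
extras (rtree/embree) are required.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


def closest_point_on_surface(mesh: trimesh.Trimesh, points: np.ndarray, k: int = 16):
    """Exact closest point on the triangulated surface for each query point.

    Candidate triangles are the ``k`` whose centroids are nearest, plus all
    triangles incident to the nearest vertex; the exact point-triangle
    projection then picks the winner.

    Returns (closest_points (n,3), distances (n,), triangle_ids (n,)).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    triangles = mesh.triangles
    n_tri = len(triangles)
    k = min(k, n_tri)
    tree = _centroid_tree(mesh)
    _, cand = tree.query(points, k=k)
    cand = cand.reshape(len(points), -1)

    vtree = _vertex_tree(mesh)
    _, nearest_vert = vtree.query(points)
    vert_faces = _vertex_faces(mesh)

    best_d2 = np.full(len(points), np.inf)
    best_pt = np.zeros((len(points), 3))
    best_tri = np.zeros(len(points), dtype=int)

    # group queries by candidate column to keep the projection vectorized
    extra = [vert_faces[v] for v in nearest_vert]
    max_extra = max((len(e) for e in extra), default=0)
    cols = [cand[:, i] for i in range(cand.shape[1])]
    for j in range(max_extra):
        col = np.array([e[j] if j < len(e) else e[0] for e in extra])
        cols.append(col)
    for col in cols:
        pts = trimesh.triangles.closest_point(triangles[col], points)
        d2 = np.einsum("ij,ij->i", pts - points, pts - points)
        upd = d2 < best_d2
        best_d2[upd] = d2[upd]
        best_pt[upd] = pts[upd]
        best_tri[upd] = col[upd]
    return best_pt, np.sqrt(best_d2), best_tri


def signed_distance(mesh: trimesh.Trimesh, points: np.ndarray, k: int = 16
                    ) -> np.ndarray:
    """Signed distance to a watertight, consistently oriented mesh.

    Negative inside.  The unsigned distance comes from exact point-triangle
    projection over a candidate set; the sign is an area-weighted
    pseudo-normal vote over all candidate triangles essentially tied for the
    closest point, which stays correct when the closest point lies on an
    edge or vertex (where a single face normal is ambiguous).
    """
    points = np.asarray(points, float).reshape(-1, 3)
    triangles = mesh.triangles
    k = min(k, len(triangles))
    tree = _centroid_tree(mesh)
    _, cand = tree.query(points, k=k)
    cand = cand.reshape(len(points), -1)

    vtree = _vertex_tree(mesh)
    _, nearest_vert = vtree.query(points)
    vert_faces = _vertex_faces(mesh)
    extra = [vert_faces[v] for v in nearest_vert]
    max_extra = max((len(e) for e in extra), default=0)
    cols = [cand[:, i] for i in range(cand.shape[1])]
    for j in range(max_extra):
        cols.append(np.array([e[j] if j < len(e) else e[0] for e in extra]))

    n_pts = len(points)
    d2 = np.empty((len(cols), n_pts))
    dots = np.empty((len(cols), n_pts))
    weights = np.empty((len(cols), n_pts))
    for i, col in enumerate(cols):
        cp = trimesh.triangles.closest_point(triangles[col], points)
        delta = points - cp
        d2[i] = np.einsum("ij,ij->i", delta, delta)
        dots[i] = np.einsum("ij,ij->i", delta, mesh.face_normals[col])
        weights[i] = mesh.area_faces[col]
    dmin2 = d2.min(axis=0)
    # vote among triangles within a whisker of the minimum distance
    tied = d2 <= dmin2[None, :] * (1 + 1e-6) + 1e-12
    vote = np.where(tied, dots * weights, 0.0).sum(axis=0)
    sign = np.where(vote >= 0, 1.0, -1.0)
    return sign * np.sqrt(dmin2)


def _centroid_tree(mesh: trimesh.Trimesh) -> cKDTree:
    cache = mesh._cache.cache
    if "_aneumorph_ctree" not in cache:
        cache["_aneumorph_ctree"] = cKDTree(mesh.triangles_center)
    return cache["_aneumorph_ctree"]


def _vertex_tree(mesh: trimesh.Trimesh) -> cKDTree:
    cache = mesh._cache.cache
    if "_aneumorph_vtree" not in cache:
        cache["_aneumorph_vtree"] = cKDTree(mesh.vertices)
    return cache["_aneumorph_vtree"]


def _vertex_faces(mesh: trimesh.Trimesh):
    cache = mesh._cache.cache
    if "_aneumorph_vfaces" not in cache:
        vf = [[] for _ in range(len(mesh.vertices))]
        for fi, face in enumerate(mesh.faces):
            for v in face:
                vf[v].append(fi)
        cache["_aneumorph_vfaces"] = [np.array(f if f else [0], dtype=int) for f in vf]
    return cache["_aneumorph_vfaces"]


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weight-interpolated percentile (q in percent).

    Order statistics are placed at the midpoints of their cumulative-weight
    intervals and linearly interpolated, so the result never exceeds the
    maximum value.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("weights sum to zero")
    mid = (cw - 0.5 * w) / total
    return float(np.interp(q / 100.0, mid, v))


def polygon_area(points: np.ndarray, normal: np.ndarray) -> float:
    """Area of a closed 3D polygon lying (approximately) in a plane."""
    points = np.asarray(points, float)
    c = points.mean(axis=0)
    d = points - c
    cross = np.cross(d, np.roll(d, -1, axis=0))
    return float(abs(0.5 * cross.sum(axis=0) @ (normal / np.linalg.norm(normal))))


def max_pairwise_distance(points2d: np.ndarray) -> float:
    """Diameter of a 2D point set (via its convex hull)."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points2d, float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def min_width(points2d: np.ndarray) -> float:
    """Minimal width of the convex hull of a 2D point set (rotating calipers)."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points2d, float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    n = len(pts)
    best = np.inf
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = np.linalg.norm(edge)
        if norm < 1e-12:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.abs((pts - pts[i]) @ normal).max()
        best = min(best, width)
    return float(best)


def section_loops(mesh: trimesh.Trimesh, plane_origin, plane_normal):
    """Closed intersection loops of a plane with a mesh, as 3D point arrays."""
    path = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if path is None:
        return []
    loops = []
    for disc in path.discrete:
        pts = np.asarray(disc, float)
        if len(pts) < 4 or not np.allclose(pts[0], pts[-1]):
            continue        # open polyline: not a closed section
        loops.append(pts[:-1])
    return loops


def loop_encloses(loop: np.ndarray, point: np.ndarray, normal: np.ndarray) -> bool:
    """Whether a closed 3D planar loop winds around a point (projected)."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    d = np.asarray(loop, float) - np.asarray(point, float)
    p = np.column_stack([d @ e1, d @ e2])
    ang = np.arctan2(p[:, 1], p[:, 0])
    dang = np.diff(np.append(ang, ang[0]))
    dang = (dang + np.pi) % (2 * np.pi) - np.pi
    return abs(dang.sum()) > np.pi


def pick_loop(loops, hint: np.ndarray):
    """The loop whose centroid is nearest a hint point (None if no loops)."""
    if not loops:
        return None
    hint = np.asarray(hint, float)
    dists = [np.linalg.norm(l.mean(axis=0) - hint) for l in loops]
    return loops[int(np.argmin(dists))]
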