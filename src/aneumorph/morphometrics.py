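"""Morphological parameters of a labeled aneurysm surface model.

Six scalar shape parameters are measured from the mesh (the seventh
morphological parameter of the comparison protocol, surface distance, lives
in :mod:`aneumorph.surface_distance`):

* **size** — maximum perpendicular height of the sac above the neck plane (mm)
* **AR** (aspect ratio) — size / average neck diameter
* **NA** (neck area) — minimum cross-sectional area of the neck (mm²)
* **PVD** (parent vessel diameter) — mean of the diameters D1 (at the
  proximal neck) and D2 (1.5×D1 further upstream) (mm)
* **SR** (size ratio) — maximum neck-centroid-to-dome distance / PVD
* **AA** (aneurysm angle) — inclination between the aneurysm axis
  (neck centroid → farthest dome point) and the neck plane (degrees)

The average neck diameter combines the maximum diameter (largest chord of the
neck curve projected into the neck plane) and the minimum diameter (minimal
caliper width of the projected curve) as their arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _meshutil as mu
from .errors import AneumorphError
from .regions import LabeledSurfaceMesh, Region


@dataclass
class NeckPlane:
    """Least-squares plane through the neck curve, normal toward the sac."""

    centroid: np.ndarray
    unit_normal: np.ndarray
    max_diameter: float
    min_diameter: float

    @property
    def average_diameter(self) -> float:
        return 0.5 * (self.max_diameter + self.min_diameter)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.centroid) @ self.unit_normal


@dataclass
class MorphoReport:
    size: float
    AR: float
    NA: float
    PVD: float
    SR: float
    AA: float
    h_max: float = float("nan")
    neck_avg_diameter: float = float("nan")
    undefined: bool = False
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "size": self.size, "AR": self.AR, "NA": self.NA, "PVD": self.PVD,
            "SR": self.SR, "AA": self.AA, "h_max": self.h_max,
            "neck_avg_diameter": self.neck_avg_diameter,
            "undefined": self.undefined, "provenance": self.provenance,
        }

    PARAMETERS = ("size", "AR", "NA", "PVD", "SR", "AA")


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _projected(points: np.ndarray, origin: np.ndarray, normal: np.ndarray):
    e1, e2 = _plane_basis(normal)
    d = np.asarray(points, float) - origin
    return np.column_stack([d @ e1, d @ e2])


def fit_neck_plane(mesh: LabeledSurfaceMesh, curve: Optional[np.ndarray] = None,
                   sac_hint: Optional[np.ndarray] = None) -> NeckPlane:
    """Fit the neck plane to the neck curve of a labeled mesh.

    The plane is the least-squares plane through the curve vertices; the
    normal is oriented toward the sac (centroid of aneurysm-region vertices,
    or an explicit ``sac_hint`` point).  Diameters are chord extremes of the
    curve projected into the plane.
    """
    if curve is None:
        curve = mesh.neck_curve if mesh is not None else None
    if curve is None or len(curve) < 3:
        raise AneumorphError("no neck curve available")
    curve = np.asarray(curve, float)
    centroid = curve.mean(axis=0)
    d = curve - centroid
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise AneumorphError("degenerate (collinear) neck curve")
    normal = vt[2]

    if sac_hint is None and mesh is not None:
        vmask = mesh.vertices_in(Region.ANEURYSM)
        if vmask.any():
            sac_hint = mesh.mesh.vertices[vmask].mean(axis=0)
    if sac_hint is not None and (np.asarray(sac_hint, float) - centroid) @ normal < 0:
        normal = -normal

    p2 = _projected(curve, centroid, normal)
    return NeckPlane(
        centroid=centroid,
        unit_normal=normal / np.linalg.norm(normal),
        max_diameter=mu.max_pairwise_distance(p2),
        min_diameter=mu.min_width(p2),
    )


def compute_size(mesh: LabeledSurfaceMesh, plane: NeckPlane) -> float:
    """Maximum perpendicular height of the aneurysm above the neck plane."""
    vmask = mesh.vertices_in(Region.ANEURYSM)
    if not vmask.any():
        return float("nan")
    return float(plane.signed_distance(mesh.mesh.vertices[vmask]).max())


def compute_NA(mesh: LabeledSurfaceMesh, plane: NeckPlane,
               max_tilt_deg: float = 10.0, n_tilt: int = 3, n_azimuth: int = 8,
               offset_fractions=(0.0, -0.03, -0.06, -0.1), return_section: bool = False):
    """Minimum neck cross-sectional area (mm²).

    The cutting plane pivots about the neck centroid; its normal is perturbed
    on a polar grid up to ``max_tilt_deg`` from the fitted plane normal, and
    small parallel offsets toward the parent (fractions of the neck diameter)
    are tried so a cut running exactly along the sac-collar crease cannot
    spoil the section; the smallest simple closed section area wins.
    Sections are evaluated on the sac-near part of the surface (aneurysm +
    neck band faces) so distant parent-vessel intersections cannot
    contaminate the cut.
    """
    # section the neck neighborhood: sac + band faces plus everything within
    # a neck-diameter ball of the centroid, so the cut cannot run along a
    # label boundary or pick up distant parent-vessel intersections
    ball = np.linalg.norm(mesh.mesh.triangles_center - plane.centroid, axis=1) \
        <= 0.9 * plane.average_diameter
    sub_mask = mesh.faces_in(Region.ANEURYSM) | mesh.faces_in(Region.NECK_BAND) | ball
    if not sub_mask.any():
        raise AneumorphError("no aneurysm/neck faces for neck-area sectioning")
    sub = mesh.submesh(sub_mask)

    e1, e2 = _plane_basis(plane.unit_normal)

    def candidate(normal, off, floor):
        origin = plane.centroid + off * plane.average_diameter * plane.unit_normal
        found = None
        for loop in mu.section_loops(sub, origin, normal):
            if not mu.loop_encloses(loop, origin, normal):
                continue
            area = mu.polygon_area(loop, normal)
            if area < floor:
                continue
            if found is None or area < found[0]:
                found = (area, loop, normal)
        return found

    # reference: straight cuts only, to anchor a sanity floor for the search
    straight = [candidate(plane.unit_normal, off, 0.0) for off in offset_fractions]
    straight = [c for c in straight if c is not None]
    if not straight:
        raise AneumorphError("neck section is not a simple closed polygon")
    best = min(straight, key=lambda c: c[0])
    floor = 0.4 * best[0]      # guards against degenerate sliver sections

    tilts = np.linspace(0.0, math.radians(max_tilt_deg), n_tilt + 1)[1:]
    for tilt in tilts:
        for az in np.linspace(0, 2 * math.pi, n_azimuth, endpoint=False):
            n = (math.cos(tilt) * plane.unit_normal
                 + math.sin(tilt) * (math.cos(az) * e1 + math.sin(az) * e2))
            for off in offset_fractions:
                cand = candidate(n, off, floor)
                if cand is not None and cand[0] < best[0]:
                    best = cand
    if return_section:
        return float(best[0]), best[1], best[2]
    return float(best[0])


def _parent_axis(mesh: LabeledSurfaceMesh):
    vmask = mesh.vertices_in(Region.PARENT_ROI) | mesh.vertices_in(Region.EXTENSION)
    if not vmask.any():
        raise AneumorphError("no parent_roi faces; cannot locate the parent vessel")
    pts = mesh.mesh.vertices[vmask]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    return center, vt[0], pts


def _section_diameters(mesh: LabeledSurfaceMesh, origin: np.ndarray, normal: np.ndarray,
                       hint: np.ndarray):
    sub_mask = (mesh.faces_in(Region.PARENT_ROI) | mesh.faces_in(Region.EXTENSION)
                | mesh.faces_in(Region.NECK_BAND))
    sub = mesh.submesh(sub_mask)
    loops = mu.section_loops(sub, origin, normal)
    loop = mu.pick_loop(loops, hint)
    if loop is None:
        raise AneumorphError("parent vessel section failed at the requested station")
    p2 = _projected(loop, origin, normal)
    dmax = mu.max_pairwise_distance(p2)
    dmin = mu.min_width(p2)
    return 0.5 * (dmax + dmin), loop


def proximal_neck_diameter(mesh: LabeledSurfaceMesh, plane: NeckPlane):
    """D1: parent diameter at the proximal edge of the neck.

    The station is offset slightly proximal of the neck footprint (a fraction
    of the neck diameter, growing until a clean closed section is found) to
    avoid the degenerate sac-vessel junction.

    Returns (d1, section_loop, center, axis, s_values, direction).
    """
    center, axis, pts = _parent_axis(mesh)
    s = (pts - center) @ axis

    if mesh.neck_curve is not None and len(mesh.neck_curve) >= 3:
        s_neck = (np.asarray(mesh.neck_curve, float) - center) @ axis
    else:
        s_neck = np.atleast_1d((plane.centroid - center) @ axis)
    # proximal = the side of the neck with the longer parent run
    lo, hi = float(s_neck.min()), float(s_neck.max())
    if (lo - s.min()) >= (s.max() - hi):
        s_edge, direction = lo, -1.0
    else:
        s_edge, direction = hi, +1.0

    scale = max(plane.average_diameter, 1e-6)
    last_err = None
    for frac in (0.15, 0.3, 0.5, 0.8):
        s1 = s_edge + direction * frac * scale
        p1 = center + s1 * axis
        try:
            d1, loop = _section_diameters(mesh, p1, axis, p1)
            return d1, loop, center, axis, s, direction
        except AneumorphError as err:
            last_err = err
    raise AneumorphError(f"could not section the proximal parent vessel: {last_err}")


def compute_PVD(mesh: LabeledSurfaceMesh, plane: NeckPlane) -> float:
    """Parent vessel diameter: mean of D1 (proximal neck) and D2 (1.5×D1 upstream).

    The parent centerline is approximated by the principal axis of the
    parent-region vertices; cross sections are cut perpendicular to it and
    measured like the neck (max chord + min caliper width, halved).
    """
    d1, loop1, center, axis, s, direction = proximal_neck_diameter(mesh, plane)
    # re-center the station on the actual section centroid (handles curvature)
    c1 = loop1.mean(axis=0)
    s2 = float((c1 - center) @ axis) + direction * 1.5 * d1
    if not (s.min() - 0.5 <= s2 <= s.max() + 0.5):
        raise AneumorphError(
            "parent_roi too short to reach the D2 station "
            f"(need station at arclength {1.5 * d1:.2f} mm upstream)")
    d2, _ = _section_diameters(mesh, center + s2 * axis, axis, center + s2 * axis)
    return float(0.5 * (d1 + d2))


def compute_SR_and_AA(mesh: LabeledSurfaceMesh, plane: NeckPlane, pvd: float):
    """Size ratio and aneurysm angle.

    H_max is the largest Euclidean distance from the neck centroid to any
    aneurysm vertex; SR = H_max / PVD.  AA is the inclination of the aneurysm
    axis (neck centroid → farthest dome vertex) with respect to the neck
    plane, in degrees in (0, 90].
    """
    vmask = mesh.vertices_in(Region.ANEURYSM)
    if not vmask.any():
        return float("nan"), float("nan")
    verts = mesh.mesh.vertices[vmask]
    d = verts - plane.centroid
    dist = np.linalg.norm(d, axis=1)
    imax = int(np.argmax(dist))
    h_max = float(dist[imax])
    axis = d[imax] / h_max
    aa = math.degrees(math.asin(min(1.0, abs(float(axis @ plane.unit_normal)))))
    if pvd <= 0 or not math.isfinite(pvd):
        return float("nan"), aa
    return h_max / pvd, aa


def morpho_report(mesh: LabeledSurfaceMesh, na_max_tilt_deg: float = 10.0,
                  provenance: Optional[dict] = None) -> MorphoReport:
    """Compute all six mesh-derived morphological parameters.

    The average neck diameter entering AR is measured on the minimal-area
    neck section found by the NA search (mid-collar), which is far more
    robust to imaging degradation than the raw neck-plane cut.
    """
    if not mesh.faces_in(Region.ANEURYSM).any():
        return MorphoReport(*(float("nan"),) * 6, undefined=True,
                            provenance=provenance or {})
    plane = fit_neck_plane(mesh)
    size = compute_size(mesh, plane)
    na, na_loop, na_normal = compute_NA(mesh, plane, max_tilt_deg=na_max_tilt_deg,
                                        return_section=True)
    p2 = _projected(na_loop, na_loop.mean(axis=0), na_normal)
    avg_d = 0.5 * (mu.max_pairwise_distance(p2) + mu.min_width(p2))
    pvd = compute_PVD(mesh, plane)
    sr, aa = compute_SR_and_AA(mesh, plane, pvd)
    vmask = mesh.vertices_in(Region.ANEURYSM)
    h_max = float(np.linalg.norm(mesh.mesh.vertices[vmask] - plane.centroid, axis=1).max())
    return MorphoReport(
        size=size,
        AR=size / avg_d,
        NA=na,
        PVD=pvd,
        SR=sr,
        AA=aa,
        h_max=h_max,
        neck_avg_diameter=avg_d,
        provenance=provenance or {},
    )
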