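"""Model reconstruction: segmentation, surface extraction, smoothing, ROI partition.

The stage mirrors a clinical vascular-modeling workflow: threshold
segmentation of the angiographic volume, region growing to keep only the
connected component of interest, isosurface extraction to a surface mesh in
world millimetres, mild smoothing, and partition of the surface into
anatomical regions (aneurysm sac, neck band, parent-vessel ROI, extensions)
relative to the neck curve.  The parent ROI extends 1.5 times the proximal
neck diameter (D1) along the centerline on each side of the neck.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from . import _meshutil as mu
from .errors import AneumorphError, SegmentationError
from .image import ImageVolume
from .regions import LabeledSurfaceMesh, Region


@dataclass
class SegmentationConfig:
    """Knobs of the reconstruction stage.

    ``threshold="auto"`` picks the midpoint between the background and lumen
    histogram modes (Otsu fallback).  ``iso_level`` is the isosurface level
    as a fraction of the threshold.  ``smoothing_sigma`` is the Taubin
    diffusion factor in (0, 1); ``smoothing_passes`` the iteration count.
    """

    threshold: Union[float, str] = "auto"
    seed_point: Optional[Tuple[float, float, float]] = None   # world mm
    smoothing_sigma: float = 0.5
    smoothing_passes: int = 10
    iso_level: float = 1.0

    def __post_init__(self):
        if self.smoothing_sigma < 0 or self.smoothing_passes < 0:
            raise AneumorphError("smoothing parameters must be >= 0")


def auto_threshold(data: np.ndarray) -> float:
    """Midpoint between the two dominant intensity modes (Otsu fallback)."""
    from scipy.signal import find_peaks
    from skimage.filters import threshold_otsu

    hist, edges = np.histogram(data.ravel(), bins=128)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # zero-pad so modes in the boundary bins (pure background / pure lumen)
    # are detectable as peaks
    padded = np.concatenate([[0.0], hist.astype(float), [0.0]])
    peaks, props = find_peaks(padded, prominence=0.005 * hist.max())
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]] - 1
        return float(centers[top2].mean())
    return float(threshold_otsu(data.ravel()))


def threshold_segment(volume: ImageVolume,
                      config: Optional[SegmentationConfig] = None) -> np.ndarray:
    """Binary mask of voxels with intensity >= threshold."""
    config = config or SegmentationConfig()
    thr = config.threshold
    if isinstance(thr, str):
        thr = auto_threshold(volume.data)
    mask = np.asarray(volume.data) >= thr
    if not mask.any():
        raise SegmentationError(f"empty segmentation at threshold {thr:g}")
    return mask


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def region_grow(mask: np.ndarray, seed_point,
                volume: Optional[ImageVolume] = None) -> np.ndarray:
    """Keep only the 26-connected component containing the seed.

    ``seed_point`` is a voxel index, or world millimetres when ``volume`` is
    given.  A seed outside the mask raises with the nearest in-mask voxel.
    """
    if volume is not None:
        idx = np.round(volume.world_to_index(seed_point)).astype(int)
    else:
        idx = np.round(np.asarray(seed_point, float)).astype(int)
    idx = tuple(int(i) for i in np.atleast_1d(idx).reshape(3))
    if not all(0 <= idx[i] < mask.shape[i] for i in range(3)):
        raise SegmentationError(f"seed voxel {idx} outside volume bounds")
    if not mask[idx]:
        inside = np.argwhere(mask)
        nearest = inside[np.argmin(((inside - np.array(idx)) ** 2).sum(axis=1))]
        hint = tuple(int(i) for i in nearest)
        if volume is not None:
            hint = tuple(np.round(volume.index_to_world(nearest), 3))
        raise SegmentationError(
            f"seed point is outside the mask; nearest in-mask voxel: {hint}")
    labels, _ = ndimage.label(mask, structure=_CONN26)
    return labels == labels[idx]


def extract_surface(volume: ImageVolume, level: Optional[float] = None,
                    mask: Optional[np.ndarray] = None,
                    pad: bool = True) -> trimesh.Trimesh:
    """Watertight isosurface mesh in world millimetres.

    ``volume`` may hold a binary mask (level defaults to 0.5) or a scalar
    intensity volume (level defaults to the auto threshold).  When ``mask``
    is given, intensities outside its dilation are reset to the minimum so
    only the selected component is meshed.  If the isosurface touches the
    volume border the data are padded (``pad=True``) or an error advises it.
    """
    data = np.asarray(volume.data, float)
    if level is None:
        level = 0.5 if data.max() <= 1.0 and set(np.unique(data)) <= {0.0, 1.0} \
            else auto_threshold(data)
    if mask is not None:
        keep = ndimage.binary_dilation(mask, structure=_CONN26, iterations=2)
        data = np.where(keep, data, data.min())
    origin = volume.origin.copy()
    border = np.concatenate([data[0].ravel(), data[-1].ravel(),
                             data[:, 0].ravel(), data[:, -1].ravel(),
                             data[:, :, 0].ravel(), data[:, :, -1].ravel()])
    if border.max() >= level:
        if not pad:
            raise AneumorphError(
                "isosurface touches the volume border; pad the volume "
                "(pad=True) to close the surface")
        data = np.pad(data, 1, constant_values=data.min())
        origin = origin - volume.spacing
    # nudge the level off any exact sample value (flat tangential surfaces
    # otherwise produce degenerate marching-cubes sheets)
    level = level - 1e-6 * (data.max() - data.min())
    verts, faces, _, _ = measure.marching_cubes(data, level=level,
                                                spacing=tuple(volume.spacing))
    mesh = trimesh.Trimesh(vertices=verts + origin, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:        # discard marching-cubes speckle components
        mesh = max(parts, key=lambda p: len(p.faces))
    mesh = _outward_oriented(mesh)
    if not mesh.is_watertight:
        raise AneumorphError("extracted surface is not watertight")
    return mesh


def _outward_oriented(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Consistently wound copy with outward normals and a fresh cache."""
    trimesh.repair.fix_normals(mesh)
    # rebuild: fix_normals can leave stale cached normals after rewinding
    mesh = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces.copy(), process=False)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
        mesh = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces.copy(),
                               process=False)
    return mesh


def smooth_surface(mesh: trimesh.Trimesh, smoothing_sigma: float = 0.5,
                   passes: int = 10) -> trimesh.Trimesh:
    """Feature-preserving Taubin smoothing (topology and vertex count kept).

    ``smoothing_sigma`` is the forward diffusion factor λ; the backward
    (dilating) factor is chosen as ν = λ/(1 − 0.05 λ) so the pass-band
    condition 0 < 1/λ − 1/ν < 0.1 holds and volume shrinkage stays small.
    Shrinkage beyond 5% emits a warning, not a failure.
    """
    out = mesh.copy()
    if passes <= 0 or smoothing_sigma <= 0:
        return out
    lam = min(smoothing_sigma, 0.9)
    trimesh.smoothing.filter_taubin(out, lamb=lam, nu=lam / (1.0 - 0.05 * lam),
                                    iterations=int(passes))
    if mesh.is_watertight and out.is_watertight and mesh.volume > 0:
        shrink = 1.0 - out.volume / mesh.volume
        if shrink > 0.05:
            warnings.warn(f"smoothing shrank the model volume by {shrink:.1%}",
                          stacklevel=2)
    return out


def extract_neck_curve(mesh: trimesh.Trimesh, plane_origin, plane_normal,
                       hint=None) -> np.ndarray:
    """Neck curve of an (unlabeled) mesh as its section with a neck plane.

    Returns the closed section loop nearest ``hint`` (default: plane origin).
    """
    loops = mu.section_loops(mesh, plane_origin, plane_normal)
    loop = mu.pick_loop(loops, plane_origin if hint is None else hint)
    if loop is None:
        raise AneumorphError("neck plane does not intersect the mesh in a closed loop")
    return loop


def partition_regions(mesh: trimesh.Trimesh, neck_curve: np.ndarray,
                      d1: Optional[float] = None,
                      sac_hint: Optional[np.ndarray] = None,
                      band_width_fraction: float = 0.1,
                      parent_extent_factor: float = 1.5) -> LabeledSurfaceMesh:
    """Partition a surface into aneurysm / neck band / parent ROI / extension.

    Faces on the sac side of the neck plane are the aneurysm; a band of
    width ``band_width_fraction × D1`` hugging the neck curve on the parent
    side is the neck band; parent faces within axial arclength
    ``parent_extent_factor × D1`` of the neck footprint are the parent ROI;
    the remainder (flow extensions, far vessel) is labeled extension.
    ``D1`` (proximal neck diameter) is estimated from a parent cross section
    when not supplied.
    """
    from .morphometrics import _parent_axis, fit_neck_plane, proximal_neck_diameter

    neck_curve = np.asarray(neck_curve, float)
    if len(neck_curve) < 3:
        raise AneumorphError("neck curve must be a closed loop of >= 3 points")
    if np.allclose(neck_curve[0], neck_curve[-1]):
        neck_curve = neck_curve[:-1]

    centroids = mesh.triangles_center
    # provisional two-way split to locate the sac and fit the plane
    plane = fit_neck_plane(None, curve=neck_curve, sac_hint=sac_hint)
    if sac_hint is None:
        # orient toward the side with the smaller attached surface area
        signed = plane.signed_distance(centroids)
        areas = mesh.area_faces
        if areas[signed > 0].sum() > areas[signed < 0].sum():
            plane.unit_normal = -plane.unit_normal
    signed = plane.signed_distance(centroids)

    labels = np.full(len(mesh.faces), LabeledSurfaceMesh.code(Region.EXTENSION),
                     dtype=np.int8)
    sac_side = signed > 0
    labels[sac_side] = LabeledSurfaceMesh.code(Region.ANEURYSM)
    labels[~sac_side] = LabeledSurfaceMesh.code(Region.PARENT_ROI)
    lmesh = LabeledSurfaceMesh(mesh, labels, neck_curve=neck_curve)

    if d1 is None:
        d1, _, _, _, _, _ = proximal_neck_diameter(lmesh, plane)

    from scipy.spatial import cKDTree

    band_w = band_width_fraction * d1
    curve_tree = cKDTree(_densify_loop(neck_curve, band_w / 4.0))
    dist_curve, _ = curve_tree.query(centroids)
    band = (~sac_side) & (dist_curve <= band_w)
    labels[band] = LabeledSurfaceMesh.code(Region.NECK_BAND)

    center, axis, _ = _parent_axis(lmesh)
    s = (centroids - center) @ axis
    s_neck = (neck_curve - center) @ axis
    span = parent_extent_factor * d1
    in_roi = (~sac_side) & (~band) & (s >= s_neck.min() - span) \
        & (s <= s_neck.max() + span)
    labels[(~sac_side) & (~band)] = LabeledSurfaceMesh.code(Region.EXTENSION)
    labels[in_roi] = LabeledSurfaceMesh.code(Region.PARENT_ROI)

    return LabeledSurfaceMesh(mesh, labels, neck_curve=neck_curve,
                              provenance={"d1": float(d1),
                                          "band_width": float(band_w),
                                          "parent_extent": float(span)})


def _densify_loop(loop: np.ndarray, max_step: float) -> np.ndarray:
    """Resample a closed polyline so consecutive points are <= max_step apart."""
    pts = []
    n = len(loop)
    for i in range(n):
        a, b = loop[i], loop[(i + 1) % n]
        steps = max(1, int(np.ceil(np.linalg.norm(b - a) / max(max_step, 1e-9))))
        for k in range(steps):
            pts.append(a + (b - a) * (k / steps))
    return np.asarray(pts)


def reconstruct_volume(volume: ImageVolume,
                       config: Optional[SegmentationConfig] = None,
                       smooth: bool = True) -> trimesh.Trimesh:
    """Full reconstruction of one volume: threshold → grow → surface → smooth."""
    config = config or SegmentationConfig()
    thr = config.threshold
    if isinstance(thr, str):
        thr = auto_threshold(volume.data)
    mask = threshold_segment(volume, SegmentationConfig(threshold=thr))
    if config.seed_point is not None:
        mask = region_grow(mask, config.seed_point, volume=volume)
    else:
        labels, n = ndimage.label(mask, structure=_CONN26)
        if n > 1:
            largest = np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1))) + 1
            mask = labels == largest
    mesh = extract_surface(volume, level=thr * config.iso_level, mask=mask)
    if smooth and config.smoothing_passes > 0:
        mesh = smooth_surface(mesh, config.smoothing_sigma, config.smoothing_passes)
    return mesh
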