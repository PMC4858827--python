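"""Synthetic aneurysm phantoms with analytic ground truth.

The phantom is a saccular aneurysm on a curved (or straight) parent vessel,
defined implicitly as the union of signed distance fields — a capped tube for
the parent artery, a sphere for the sac, and (for tilted sacs) a short
oblique neck stalk — and meshed by marching-cubes isosurface extraction at
level zero.  This gives closed-form ground truth for every morphological
parameter together with a watertight, consistently oriented mesh.

The module also renders modality-degraded image volumes of the phantom
(voxel spacing, point-spread blur and noise emulating rotational
angiography, CT angiography and MR angiography acquisitions), provides
inlet-waveform and boundary-condition helpers, and synthesizes pulsatile
wall-shear-stress fields standing in for a CFD solve, patterned with low
time-averaged WSS on the dome, oscillatory (high-OSI) shear on the sac body
and a steep WSS gradient across the neck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import trimesh
from skimage import measure

from . import _meshutil as mu
from .errors import ConfigurationError, ConstructiveGeometryError
from .hemodynamics import WSSField
from .image import ImageVolume
from .morphometrics import MorphoReport, fit_neck_plane
from .regions import LabeledSurfaceMesh, Region


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass
class AneurysmSpec:
    """Parametric description of a saccular-aneurysm phantom (lengths in mm)."""

    parent_radius: float = 2.0
    parent_length: float = 24.0
    parent_curvature: float = 0.0       # 1/mm; 0 = straight tube
    sac_radius: float = 3.0
    neck_radius: float = 1.5
    sac_offset_angle: float = 0.0       # degrees tilt of sac axis from neck normal
    mesh_edge_length: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.parent_radius <= 0 or self.parent_length <= 0:
            raise ConfigurationError("parent dimensions must be positive")
        if self.sac_radius < 0:
            raise ConfigurationError("sac_radius must be >= 0")
        if self.sac_radius > 0 and not 0 < self.neck_radius <= self.sac_radius:
            raise ConfigurationError("need 0 < neck_radius <= sac_radius")
        if self.mesh_edge_length <= 0:
            raise ConfigurationError("mesh_edge_length must be positive")
        if self.parent_curvature < 0:
            raise ConfigurationError("parent_curvature must be >= 0")
        if self.parent_curvature > 0 and \
                self.parent_length * self.parent_curvature >= 2 * math.pi:
            raise ConfigurationError("curved parent would wrap onto itself")
        if not 0 <= self.sac_offset_angle < 60:
            raise ConfigurationError("sac_offset_angle must be in [0, 60) degrees")


@dataclass
class ModalityProfile:
    """Imaging characteristics of one angiographic modality."""

    name: str
    voxel_spacing: Tuple[float, float, float]
    psf_sigma: float            # mm, Gaussian point-spread
    noise_sigma: float          # fraction of lumen-background contrast
    lumen_intensity: float = 1.0
    background_intensity: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        self.voxel_spacing = tuple(float(s) for s in np.broadcast_to(
            np.asarray(self.voxel_spacing, float), (3,)))
        if min(self.voxel_spacing) <= 0:
            raise ConfigurationError("voxel_spacing must be positive")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ConfigurationError("psf/noise sigmas must be >= 0")
        if self.lumen_intensity <= self.background_intensity:
            raise ConfigurationError("lumen intensity must exceed background")


def default_modality_profiles(rng_seed: int = 0) -> dict:
    """The three default modality profiles, best (3DRA-like) to worst (MRA-like)."""
    return {
        "DRA_like": ModalityProfile("DRA_like", (0.15, 0.15, 0.15), 0.10, 0.01,
                                    rng_seed=rng_seed),
        "CTA_like": ModalityProfile("CTA_like", (0.40, 0.40, 0.40), 0.30, 0.03,
                                    rng_seed=rng_seed),
        "MRA_like": ModalityProfile("MRA_like", (0.50, 0.50, 0.50), 0.45, 0.05,
                                    rng_seed=rng_seed),
    }


@dataclass
class Waveform:
    """Pulsatile inlet volume-flow waveform over one cardiac cycle.

    ``times`` are seconds covering [0, T] inclusive; first and last flow
    samples must agree (periodicity).  Flow rates are mm³/s.
    """

    times: np.ndarray
    flow_rates: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.flow_rates = np.asarray(self.flow_rates, float)
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("waveform times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > self.period + 1e-12:
            raise ConfigurationError("waveform times must lie within [0, T]")
        if not math.isclose(self.flow_rates[0], self.flow_rates[-1],
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigurationError("waveform must be periodic (q(0) == q(T))")

    def q_at(self, t) -> np.ndarray:
        """Flow rate at time t (periodic linear interpolation)."""
        t = np.mod(np.asarray(t, float), self.period)
        return np.interp(t, self.times, self.flow_rates)

    @property
    def t_peak(self) -> float:
        return float(self.times[int(np.argmax(self.flow_rates))])

    @property
    def q_mean(self) -> float:
        T = self.times[-1] - self.times[0]
        return float(np.trapezoid(self.flow_rates, self.times) / T)

    def save_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.flow_rates]),
                   delimiter=",", header="t_seconds,q_mm3_per_s", comments="")

    @classmethod
    def load_csv(cls, path) -> "Waveform":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=arr[:, 0], flow_rates=arr[:, 1], period=float(arr[-1, 0]))


def default_waveform(period: float = 0.8, n_samples: int = 32,
                     q_mean: float = 3800.0) -> Waveform:
    """ICA-like two-harmonic positive pulse (a documented stand-in waveform).

    q_mean defaults to 3.8 mL/s so that a 4 mm inlet sees a peak Reynolds
    number near the middle of the physiological 500–750 range.  The cycle
    starts and ends at the diastolic minimum, with peak systole mid-cycle.
    """
    t = np.linspace(0.0, period, n_samples + 1)
    phase = 2 * math.pi * t / period
    q = q_mean * (1.0 + 0.55 * np.sin(phase - math.pi / 2)
                  + 0.15 * np.sin(2 * phase + math.pi / 4))
    q[-1] = q[0]
    return Waveform(times=t, flow_rates=q, period=period)


@dataclass
class InletSpec:
    """Inlet geometry and fluid constants for boundary-condition helpers."""

    diameter: float                      # mm
    fluid_density: float = 1056.0        # kg/m^3
    fluid_viscosity: float = 0.0035      # Pa*s
    outflow_split: Tuple[float, float] = (0.65, 0.35)   # MCA:ACA

    def __post_init__(self):
        if self.diameter <= 0:
            raise ConfigurationError("inlet diameter must be positive")
        s = self.outflow_split
        if min(s) <= 0 or not math.isclose(sum(s), 1.0, rel_tol=1e-9):
            raise ConfigurationError("outflow split must be positive and sum to 1")


def inlet_mean_velocity(waveform: Waveform, inlet: InletSpec, t) -> np.ndarray:
    """Mean inlet velocity v(t) = q(t) / (π (d/2)²), in mm/s."""
    area = math.pi * (inlet.diameter / 2.0) ** 2
    return waveform.q_at(t) / area


def peak_reynolds(waveform: Waveform, inlet: InletSpec) -> float:
    """Peak Reynolds number Re = ρ v d / μ (mm converted to m internally)."""
    v_peak = float(np.max(waveform.flow_rates)) / (math.pi * (inlet.diameter / 2) ** 2)
    return (inlet.fluid_density * (v_peak * 1e-3)
            * (inlet.diameter * 1e-3) / inlet.fluid_viscosity)


@dataclass
class WSSSynthesisSpec:
    """Controls for the synthetic pulsatile WSS field."""

    base_magnitude: float = 4.0            # Pa, parent-vessel level
    dome_attenuation: float = 0.15         # (0, 1]: dome AWSS fraction of base
    neck_gradient_scale: float = 8.0       # Pa/mm ramp across the neck band
    body_oscillation_fraction: float = 0.8  # [0, 1] reversing component weight
    n_timesteps: int = 32
    rng_seed: int = 0
    direction_jitter: float = 0.03         # radians, static per-vertex jitter

    def __post_init__(self):
        if self.n_timesteps < 8:
            raise ConfigurationError("n_timesteps must be >= 8")
        if not 0 < self.dome_attenuation <= 1:
            raise ConfigurationError("dome_attenuation must be in (0, 1]")
        if not 0 <= self.body_oscillation_fraction <= 1:
            raise ConfigurationError("body_oscillation_fraction must be in [0, 1]")
        if self.base_magnitude <= 0 or self.neck_gradient_scale < 0:
            raise ConfigurationError("magnitudes must be positive")


# --------------------------------------------------------------------------
# implicit geometry
# --------------------------------------------------------------------------

class PhantomGeometry:
    """Implicit (signed-distance) representation of one phantom.

    Frame: the parent centerline passes through the origin heading along +x;
    the sac sits on top (+z).  The ground-truth neck plane passes through the
    anchor point with normal +z (sac side), independent of sac tilt.
    """

    def __init__(self, spec: AneurysmSpec):
        self.spec = spec
        a, R, rn = spec.parent_radius, spec.sac_radius, spec.neck_radius
        theta = math.radians(spec.sac_offset_angle)
        self.theta = theta
        self.u = np.array([math.sin(theta), 0.0, math.cos(theta)])
        self.has_sac = R > 0
        if self.has_sac:
            self.b = math.sqrt(R * R - rn * rn)
            # the neck plane sits a small clearance above the tube so the
            # neck circle is a clean transversal curve (no tangency between
            # plane and vessel wall); the sac connects through a neck stalk
            # whose collar below the plane is a proper cylindrical neck
            self.lift = 0.5 * rn
            self.anchor = np.array([0.0, 0.0, a + self.lift])
            if theta > 0:
                # stalk long enough that (a) the oblique neck section stays
                # on the stalk and (b) the sphere clears the neck plane
                self.stalk_len = max(1.5 * rn * math.tan(theta),
                                     1.05 * R / math.cos(theta) - self.b)
            else:
                self.stalk_len = 0.0
            self.sac_center = self.anchor + (self.stalk_len + self.b) * self.u
        else:
            self.b = 0.0
            self.lift = 0.0
            self.stalk_len = 0.0
            self.anchor = np.array([0.0, 0.0, a])
            self.sac_center = None

    # ------------------------------------------------------------ SDF
    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Union signed distance (negative inside the lumen)."""
        p = np.asarray(points, float).reshape(-1, 3)
        spec = self.spec
        a = spec.parent_radius
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        if spec.parent_curvature > 0:
            rc = 1.0 / spec.parent_curvature
            ring = np.sqrt(x * x + (z + rc) ** 2)
            d_tube = np.sqrt((ring - rc) ** 2 + y * y) - a
            arc = np.abs(np.arctan2(x, z + rc)) * rc
            d_tube = np.maximum(d_tube, arc - spec.parent_length / 2.0)
        else:
            d_tube = np.sqrt(y * y + z * z) - a
            d_tube = np.maximum(d_tube, np.abs(x) - spec.parent_length / 2.0)
        d = d_tube
        if self.has_sac:
            d_sac = np.linalg.norm(p - self.sac_center, axis=1) - spec.sac_radius
            d = np.minimum(d, d_sac)
            # neck stalk (capsule): always present; below the plane it forms
            # the collar joining sac and vessel, above the plane its rounded
            # cap is submerged inside the sac sphere
            rn = spec.neck_radius
            # lower end just deep enough to merge with the vessel lumen
            a0 = self.anchor - ((self.lift + rn) / math.cos(self.theta)) * self.u
            # the stalk end sits slightly above the neck plane so its cap is
            # strictly submerged in the sphere (no grazing-contact surface)
            seg = self.anchor + (self.stalk_len + 0.05 * rn) * self.u - a0
            seg_len2 = seg @ seg
            t = np.clip(((p - a0) @ seg) / seg_len2, 0.0, 1.0)
            closest = a0 + t[:, None] * seg
            d_stalk = np.linalg.norm(p - closest, axis=1) - rn
            d = np.minimum(d, d_stalk)
        return d

    # ------------------------------------------------------- ground truth
    @property
    def neck_plane_origin(self) -> np.ndarray:
        return self.anchor

    @property
    def neck_plane_normal(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def neck_curve(self, n_points: int = 256) -> np.ndarray:
        """Analytic neck curve: sphere circle (no tilt) or oblique stalk ellipse."""
        if not self.has_sac:
            raise ConstructiveGeometryError("phantom has no sac, hence no neck")
        rn = self.spec.neck_radius
        psi = np.linspace(0, 2 * math.pi, n_points, endpoint=False)
        if self.theta == 0:
            return self.anchor + rn * np.column_stack(
                [np.cos(psi), np.sin(psi), np.zeros_like(psi)])
        e1 = np.array([math.cos(self.theta), 0.0, -math.sin(self.theta)])
        e2 = np.array([0.0, 1.0, 0.0])
        t = rn * np.cos(psi) * math.tan(self.theta)
        return (self.anchor + t[:, None] * self.u
                + rn * np.cos(psi)[:, None] * e1 + rn * np.sin(psi)[:, None] * e2)

    def ground_truth(self, na_search_deg: float = 10.0) -> MorphoReport:
        """Closed-form morphological ground truth of the phantom."""
        spec = self.spec
        if not self.has_sac:
            return MorphoReport(*(float("nan"),) * 6, undefined=True,
                                provenance={"phantom": "parent-only"})
        R, rn, a = spec.sac_radius, spec.neck_radius, spec.parent_radius
        s, b, th = self.stalk_len, self.b, self.theta
        size = (s + b) * math.cos(th) + R
        h_max = s + b + R
        pvd = 2.0 * a
        # NA and the neck diameters are those of the minimal neck section:
        # the tilt search reduces the cut's obliquity to the stalk axis to
        # at most the residual angle
        residual = max(th - math.radians(na_search_deg), 0.0)
        na = math.pi * rn * rn / math.cos(residual)
        avg_d = rn * (1.0 + 1.0 / math.cos(residual))
        return MorphoReport(
            size=size, AR=size / avg_d, NA=na, PVD=pvd,
            SR=h_max / pvd, AA=90.0 - spec.sac_offset_angle,
            h_max=h_max, neck_avg_diameter=avg_d,
            provenance={"phantom": "closed-form ground truth"},
        )


# --------------------------------------------------------------------------
# meshing
# --------------------------------------------------------------------------

def _phantom_bounds(geom: PhantomGeometry, margin: float):
    spec = geom.spec
    a, L = spec.parent_radius, spec.parent_length
    if spec.parent_curvature > 0:
        rc = 1.0 / spec.parent_curvature
        phi = L / (2 * rc)
        xext = (rc + a) * math.sin(min(phi, math.pi / 2))
        zlo = -min(rc * (1 - math.cos(phi)) + a, 2 * rc)
    else:
        xext, zlo = L / 2, -a
    lo = np.array([-xext, -a, zlo], float)
    hi = np.array([xext, a, a], float)
    if geom.has_sac:
        c, R = geom.sac_center, spec.sac_radius
        lo = np.minimum(lo, c - R)
        hi = np.maximum(hi, c + R)
        rn = spec.neck_radius
        stalk_lo = geom.anchor - (geom.lift + rn) / math.cos(geom.theta) * geom.u
        lo = np.minimum(lo, stalk_lo - rn)
        hi = np.maximum(hi, stalk_lo + rn)
    return lo - margin, hi + margin


def build_phantom_mesh(spec: AneurysmSpec,
                       band_width_fraction: float = 0.1,
                       parent_extent_factor: float = 1.5,
                       ) -> Tuple[LabeledSurfaceMesh, MorphoReport]:
    """Mesh the implicit phantom and return it with its analytic ground truth.

    The isosurface is extracted by marching cubes on a grid of spacing
    ``mesh_edge_length``; faces are partitioned into aneurysm / neck band /
    parent ROI / extension using the analytic neck curve and plane.
    """
    from .reconstruction import partition_regions

    geom = PhantomGeometry(spec)
    h = spec.mesh_edge_length
    lo, hi = _phantom_bounds(geom, margin=3 * h)
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    if np.prod(shape) > 6e7:
        raise ConstructiveGeometryError("phantom grid too large; coarsen mesh_edge_length")
    axes = [lo[i] + h * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sdf = geom.signed_distance(grid.reshape(-1, 3)).reshape(grid.shape[:3])

    # a negligible level shift avoids degenerate cells where grid samples
    # land exactly on the zero isosurface (lattice-aligned tube walls)
    verts, faces, _, _ = measure.marching_cubes(sdf, level=-1e-6, spacing=(h, h, h))
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda p: len(p.faces))
    from .reconstruction import _outward_oriented

    mesh = _outward_oriented(mesh)
    if not mesh.is_watertight:
        raise ConstructiveGeometryError("phantom isosurface is not watertight")

    truth = geom.ground_truth()
    if not geom.has_sac:
        labels = np.full(len(mesh.faces), LabeledSurfaceMesh.code(Region.PARENT_ROI),
                         dtype=np.int8)
        lmesh = LabeledSurfaceMesh(mesh, labels, neck_curve=None,
                                   provenance={"phantom_spec": vars(spec).copy()})
        return lmesh, truth

    curve = geom.neck_curve()
    lmesh = partition_regions(
        mesh, curve,
        d1=2 * spec.parent_radius,
        sac_hint=geom.sac_center,
        band_width_fraction=band_width_fraction,
        parent_extent_factor=parent_extent_factor,
    )
    lmesh.provenance["phantom_spec"] = vars(spec).copy()
    return lmesh, truth


# --------------------------------------------------------------------------
# modality imaging
# --------------------------------------------------------------------------

def voxelize(obj, profile: ModalityProfile,
             feature_size: Optional[float] = None) -> ImageVolume:
    """Render a modality-degraded image volume of a phantom or mesh.

    The lumen is rendered as one-voxel-wide linear partial-volume occupancy
    of the signed distance (a scanner integrates intensity over each voxel),
    scaled between background and lumen intensity, blurred with a Gaussian
    point-spread of ``psf_sigma`` and degraded with seeded Gaussian noise.
    Deterministic given ``profile.rng_seed``.  The grid is anchored to
    multiples of the voxel spacing in world coordinates.
    """
    from scipy.ndimage import gaussian_filter

    spacing = np.asarray(profile.voxel_spacing, float)
    if isinstance(obj, PhantomGeometry):
        sdf_fn = obj.signed_distance
        lo, hi = _phantom_bounds(obj, margin=0.0)
        feature_size = feature_size or (obj.spec.neck_radius if obj.has_sac
                                        else obj.spec.parent_radius)
    elif isinstance(obj, AneurysmSpec):
        return voxelize(PhantomGeometry(obj), profile, feature_size)
    elif hasattr(obj, "signed_distance") and hasattr(obj, "bounds"):
        sdf_fn = obj.signed_distance
        lo, hi = np.asarray(obj.bounds, float)
    else:
        mesh = obj.mesh if isinstance(obj, LabeledSurfaceMesh) else obj
        sdf_fn = lambda pts: mu.signed_distance(mesh, pts)  # noqa: E731
        lo, hi = mesh.bounds
    margin = 2 * spacing + 3 * profile.psf_sigma
    lo = np.floor((lo - margin) / spacing) * spacing
    hi = np.ceil((hi + margin) / spacing) * spacing
    shape = np.round((hi - lo) / spacing).astype(int) + 1
    if np.prod(shape) > 6e7:
        raise ConfigurationError("image grid too large for this spacing")
    axes = [lo[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sdf = sdf_fn(grid.reshape(-1, 3)).reshape(tuple(shape))

    # partial-volume ramp ~1.5 voxels wide: wide enough that the lumen
    # boundary is sampled by neighboring voxels in every direction
    ramp = 1.5 * float(np.mean(spacing))
    occupancy = np.clip(0.5 - sdf / ramp, 0.0, 1.0)
    contrast = profile.lumen_intensity - profile.background_intensity
    data = profile.background_intensity + contrast * occupancy
    if profile.psf_sigma > 0:
        data = gaussian_filter(data, sigma=profile.psf_sigma / spacing)
    provenance = {"modality": profile.name, "profile": {
        "voxel_spacing": list(profile.voxel_spacing), "psf_sigma": profile.psf_sigma,
        "noise_sigma": profile.noise_sigma, "rng_seed": profile.rng_seed}}
    if feature_size is not None and max(spacing) > feature_size:
        provenance["warnings"] = [
            f"voxel spacing {max(spacing):.3g} mm exceeds smallest feature "
            f"{feature_size:.3g} mm"]
    if profile.noise_sigma > 0:
        rng = np.random.default_rng(profile.rng_seed)
        data = data + rng.normal(0.0, profile.noise_sigma * contrast, size=data.shape)
    return ImageVolume(data=data.astype(np.float32), spacing=spacing, origin=lo,
                       provenance=provenance)


# --------------------------------------------------------------------------
# WSS synthesis (stands in for the CFD solve)
# --------------------------------------------------------------------------

def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def synthesize_wss(lmesh: LabeledSurfaceMesh, waveform: Waveform,
                   spec: Optional[WSSSynthesisSpec] = None) -> WSSField:
    """Synthesize a periodic pulsatile WSS vector field on a labeled mesh.

    The field is tangential, scales with the instantaneous waveform, and is
    spatially patterned so that the dome carries attenuated (low) AWSS, the
    sac body a direction-reversing (high-OSI) component, and the neck band a
    steep tangential magnitude ramp (high AWSSG).  Exactly periodic over the
    cycle and deterministic given ``spec.rng_seed``.
    """
    spec = spec or WSSSynthesisSpec()
    mesh = lmesh.mesh
    n_v = len(mesh.vertices)
    amask = lmesh.vertices_in(Region.ANEURYSM)
    has_sac = lmesh.faces_in(Region.ANEURYSM).any()
    if not has_sac and not lmesh.faces_in(Region.PARENT_ROI).any():
        raise ConfigurationError("mesh has neither aneurysm nor parent regions")

    # base tangential direction: bulk flow direction projected on the surface
    pmask = lmesh.vertices_in(Region.PARENT_ROI) | lmesh.vertices_in(Region.EXTENSION)
    pts = mesh.vertices[pmask if pmask.any() else slice(None)]
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
    flow_dir = vt[0]
    normals = mesh.vertex_normals
    tang = flow_dir[None, :] - (normals @ flow_dir)[:, None] * normals
    bad = np.linalg.norm(tang, axis=1) < 1e-6
    if bad.any():
        alt = np.array([0.0, 1.0, 0.0])
        tang[bad] = alt - (normals[bad] @ alt)[:, None] * normals[bad]
    tang /= np.linalg.norm(tang, axis=1)[:, None]

    # static per-vertex direction jitter (rotation about the vertex normal)
    if spec.direction_jitter > 0:
        rng = np.random.default_rng(spec.rng_seed)
        ang = rng.normal(0.0, spec.direction_jitter, n_v)
        t2 = np.cross(normals, tang)
        tang = np.cos(ang)[:, None] * tang + np.sin(ang)[:, None] * t2
        tang /= np.linalg.norm(tang, axis=1)[:, None]

    # static magnitude profile
    amp = np.ones(n_v)
    osc_weight = np.zeros(n_v)
    if has_sac:
        plane = fit_neck_plane(lmesh)
        height = plane.signed_distance(mesh.vertices)
        h_sac = height[amask]
        h_max = float(h_sac.max()) if h_sac.size else 1.0
        xi = np.clip(height / max(h_max, 1e-9), 0.0, 1.0)
        # dome attenuation, smoothly ramped with height above the neck plane
        amp_sac = 1.0 - (1.0 - spec.dome_attenuation) * _smoothstep((xi - 0.15) / 0.45)
        amp[amask] = amp_sac[amask]
        # reversing component on the sac body (lower half of the sac)
        osc_weight[amask] = (spec.body_oscillation_fraction
                             * _smoothstep((0.55 - xi[amask]) / 0.35))
        # steep tangential ramp across the neck band (parent side of the curve)
        bmask = lmesh.vertices_in(Region.NECK_BAND)
        if bmask.any():
            below = np.clip(-height[bmask], 0.0, None)
            width = max(float(below.max()), 1e-9)
            ramp = (spec.neck_gradient_scale / spec.base_magnitude) * (width - below)
            amp[bmask] = np.maximum(amp[bmask], 1.0) + ramp

    times = np.linspace(0.0, waveform.period, spec.n_timesteps + 1)
    m = waveform.q_at(times) / waveform.q_mean
    phase = np.cos(2 * math.pi * times / waveform.period)
    steady = (1.0 - osc_weight)[None, :] * m[:, None]
    reversing = osc_weight[None, :] * (m[:, None] * phase[:, None])
    coeff = spec.base_magnitude * amp[None, :] * (steady + reversing)
    vectors = coeff[:, :, None] * tang[None, :, :]
    vectors[-1] = vectors[0]        # enforce exact periodicity

    return WSSField(
        mesh_ref=lmesh, times=times, vectors=vectors, period=waveform.period,
        t_peak_systole=float(times[int(np.argmax(m))]),
        t_end_diastole=float(times[-1]),
    )


def aneurysm_subregions(lmesh: LabeledSurfaceMesh):
    """Vertex masks for the sac dome (upper half) and body (lower half)."""
    amask = lmesh.vertices_in(Region.ANEURYSM)
    plane = fit_neck_plane(lmesh)
    height = plane.signed_distance(lmesh.mesh.vertices)
    h_max = float(height[amask].max())
    dome = amask & (height >= 0.5 * h_max)
    body = amask & (height < 0.5 * h_max)
    return dome, body
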