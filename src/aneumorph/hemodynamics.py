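"""Hemodynamic wall-shear-stress statistics on triangulated lumen surfaces.

Three per-vertex maps are derived from a time-resolved WSS vector field
sampled over one cardiac cycle of period ``T``:

* ``AWSS = |(1/T) ∫ WSS dt|`` — magnitude of the time-averaged vector (Pa);
* ``OSI = ½ (1 − |(1/T) ∫ WSS dt| / ((1/T) ∫ |WSS| dt))`` — oscillatory
  shear index, 0 for a unidirectional field, 0.5 for full reversal;
* ``AWSSG = (1/T) ∫ √(|∇WSSx|² + |∇WSSy|² + |∇WSSz|²) dt`` — cycle average
  of the instantaneous tangential-gradient magnitude (Pa/mm).  Spatial
  gradients use per-triangle linear shape functions averaged to vertices
  with triangle-area weights.

Regional statistics reduce these maps over the labeled aneurysm and parent
regions with barycentric vertex-area weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from . import _meshutil as mu
from .errors import AneumorphError, ConfigurationError
from .regions import LabeledSurfaceMesh, Region


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class WSSField:
    """Per-vertex time-resolved wall shear stress over one cardiac cycle.

    ``vectors`` has shape (n_times, n_vertices, 3) in Pa; ``times`` are
    strictly increasing seconds in [0, T].  If the last sample sits at T the
    field is stored closed (periodic endpoint included); otherwise the cycle
    integral wraps the first sample around.
    """

    mesh_ref: Optional[LabeledSurfaceMesh]
    times: np.ndarray
    vectors: np.ndarray
    period: float
    t_peak_systole: float
    t_end_diastole: float

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_times, n_vertices, 3)")
        if len(self.times) != self.vectors.shape[0]:
            raise ValueError("times and vectors disagree on sample count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > self.period + 1e-12:
            raise ValueError("times must lie within [0, T]")
        if self.mesh_ref is not None and \
                self.vectors.shape[1] != len(self.mesh_ref.mesh.vertices):
            raise ValueError("vector array inconsistent with mesh vertex count")

    @property
    def n_vertices(self) -> int:
        return self.vectors.shape[1]

    def _closed(self):
        """times/vectors covering the closed cycle [0, T]."""
        if abs(self.times[-1] - self.period) <= 1e-9 * max(self.period, 1.0):
            return self.times, self.vectors
        times = np.append(self.times, self.times[0] + self.period)
        vectors = np.concatenate([self.vectors, self.vectors[:1]], axis=0)
        return times, vectors

    def at_time(self, t: float) -> np.ndarray:
        """Vectors at time t (snapped to the nearest stored sample)."""
        times, vectors = self._closed()
        return vectors[int(np.argmin(np.abs(times - t)))]

    # ---------------------------------------------------------------- I/O
    def save(self, directory) -> None:
        """One legacy-VTK ASCII point-data file per timestep + JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        verts = (self.mesh_ref.mesh.vertices if self.mesh_ref is not None
                 else np.zeros((self.n_vertices, 3)))
        for i, t in enumerate(self.times):
            name = f"wss_{i:04d}.vtk"
            names.append(name)
            _write_vtk_points(directory / name, verts, self.vectors[i])
        manifest = {
            "period": self.period,
            "times": self.times.tolist(),
            "t_peak_systole": self.t_peak_systole,
            "t_end_diastole": self.t_end_diastole,
            "files": names,
        }
        (directory / "wss_manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory, mesh_ref: Optional[LabeledSurfaceMesh] = None) -> "WSSField":
        directory = Path(directory)
        manifest = json.loads((directory / "wss_manifest.json").read_text())
        vectors = np.stack([_read_vtk_vectors(directory / name)
                            for name in manifest["files"]])
        return cls(
            mesh_ref=mesh_ref,
            times=np.array(manifest["times"], float),
            vectors=vectors,
            period=float(manifest["period"]),
            t_peak_systole=float(manifest["t_peak_systole"]),
            t_end_diastole=float(manifest["t_end_diastole"]),
        )


def _write_vtk_points(path, points, vectors):
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nwss field\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.7g} {p[1]:.7g} {p[2]:.7g}\n")
        fh.write(f"POINT_DATA {len(points)}\nVECTORS wss float\n")
        for v in vectors:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")


def _read_vtk_vectors(path) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    idx = next(i for i, l in enumerate(lines) if l.startswith("VECTORS"))
    n = int(next(l for l in lines if l.startswith("POINT_DATA")).split()[1])
    return np.array([[float(x) for x in lines[idx + 1 + j].split()] for j in range(n)])


@dataclass
class HemoConfig:
    """Thresholds for the derived regional statistics."""

    low_wss_threshold: float = 0.4     # Pa
    high_osi_threshold: float = 0.2
    wss_percentile: float = 90.0

    def __post_init__(self):
        if self.low_wss_threshold <= 0 or self.high_osi_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if not 0 < self.wss_percentile < 100:
            raise ConfigurationError("percentile must be in (0, 100)")


@dataclass
class HemoReport:
    """The nine regional hemodynamic parameters (A = aneurysm, P = parent)."""

    AWSS_A: float
    AWSS_P: float
    LWSS_A: float
    MWSS_A: float
    WSS90_A: float
    OSI_A: float
    MOSI_A: float
    HOSI_A: float
    AWSSG_A: float
    provenance: dict = field(default_factory=dict)

    PARAMETERS = ("AWSS_A", "AWSS_P", "LWSS_A", "MWSS_A", "WSS90_A",
                  "OSI_A", "MOSI_A", "HOSI_A", "AWSSG_A")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.PARAMETERS}
        d["provenance"] = self.provenance
        return d


# --------------------------------------------------------------------------
# pointwise cycle statistics
# --------------------------------------------------------------------------

def _cycle_integrals(field: WSSField):
    times, vectors = field._closed()
    if len(times) < 3:
        raise AneumorphError("need at least 3 time samples for cycle integrals")
    T = times[-1] - times[0]
    mean_vec = np.trapezoid(vectors, times, axis=0) / T
    mean_mag = np.trapezoid(np.linalg.norm(vectors, axis=2), times, axis=0) / T
    return mean_vec, mean_mag


def time_average_wss(field: WSSField) -> np.ndarray:
    """Per-vertex AWSS (Pa): magnitude of the trapezoidal time-mean vector."""
    mean_vec, _ = _cycle_integrals(field)
    return np.linalg.norm(mean_vec, axis=1)


def oscillatory_shear_index(times, vectors, period: float) -> np.ndarray:
    """OSI from raw arrays (n_times, n_vertices, 3); see module docstring."""
    field = WSSField(mesh_ref=None, times=times, vectors=vectors, period=period,
                     t_peak_systole=float(np.asarray(times)[0]),
                     t_end_diastole=float(np.asarray(times)[-1]))
    return compute_osi(field)


def compute_osi(field: WSSField) -> np.ndarray:
    """Per-vertex OSI in [0, 0.5]; identically-zero WSS vertices report 0."""
    mean_vec, mean_mag = _cycle_integrals(field)
    num = np.linalg.norm(mean_vec, axis=1)
    osi = np.zeros_like(mean_mag)
    ok = mean_mag > 0
    osi[ok] = 0.5 * (1.0 - num[ok] / mean_mag[ok])
    return np.clip(osi, 0.0, 0.5)


# --------------------------------------------------------------------------
# surface gradients
# --------------------------------------------------------------------------

def surface_gradient(mesh: trimesh.Trimesh, values: np.ndarray) -> np.ndarray:
    """Per-vertex tangential gradient of a per-vertex scalar (units/mm).

    Each triangle contributes its exact linear-shape-function gradient,
    averaged to vertices with triangle-area weights.  Degenerate (zero-area)
    triangles are excluded.
    """
    if isinstance(mesh, LabeledSurfaceMesh):
        mesh = mesh.mesh
    values = np.asarray(values, float)
    tri = mesh.faces
    v = mesh.vertices
    p0, p1, p2 = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    f0, f1, f2 = values[tri[:, 0]], values[tri[:, 1]], values[tri[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(n, axis=1)            # 2 * area
    good = a2 > 1e-14
    nhat = np.zeros_like(n)
    nhat[good] = n[good] / a2[good, None]
    # ∇f = ( Δf1 · (e2 × n̂) + Δf2 · (n̂ × e1) ) / |n|  with e1=p1−p0, e2=p2−p0
    grad = ((f1 - f0)[:, None] * np.cross(p2 - p0, nhat)
            + (f2 - f0)[:, None] * np.cross(nhat, p1 - p0))
    grad[good] /= a2[good, None]
    grad[~good] = 0.0

    areas = 0.5 * a2
    vgrad = np.zeros((len(v), 3))
    wsum = np.zeros(len(v))
    for k in range(3):
        np.add.at(vgrad, tri[:, k], grad * areas[:, None])
        np.add.at(wsum, tri[:, k], areas)
    wsum[wsum == 0] = 1.0
    return vgrad / wsum[:, None]


def compute_awssg(field: WSSField) -> np.ndarray:
    """Per-vertex AWSSG (Pa/mm): cycle average of the instantaneous
    root-sum-square gradient magnitude of the three WSS components."""
    if field.mesh_ref is None:
        raise AneumorphError("AWSSG needs the mesh geometry (mesh_ref is None)")
    mesh = field.mesh_ref.mesh
    times, vectors = field._closed()
    T = times[-1] - times[0]
    inst = np.empty((len(times), vectors.shape[1]))
    for i in range(len(times)):
        g2 = np.zeros(vectors.shape[1])
        for c in range(3):
            g = surface_gradient(mesh, vectors[i, :, c])
            g2 += np.einsum("ij,ij->i", g, g)
        inst[i] = np.sqrt(g2)
    return np.trapezoid(inst, times, axis=0) / T


# --------------------------------------------------------------------------
# regional statistics
# --------------------------------------------------------------------------

def regional_statistics(field: WSSField, config: Optional[HemoConfig] = None,
                        provenance: Optional[dict] = None) -> HemoReport:
    """All nine regional parameters from a WSS field on a labeled mesh.

    Aneurysm statistics are area-weighted over aneurysm-region vertices
    (vertex area = one third of incident triangle areas); "portion of wall"
    statistics are area fractions.  MWSS/WSS90 are taken at peak systole,
    LWSS at end diastole; OSI-derived parameters use the cycle-integrated
    OSI map.
    """
    config = config or HemoConfig()
    lmesh = field.mesh_ref
    if lmesh is None:
        raise AneumorphError("regional statistics need a labeled mesh")
    for region in (Region.ANEURYSM, Region.PARENT_ROI):
        if not lmesh.faces_in(region).any():
            raise AneumorphError(f"mesh has no faces labeled {region.value}")

    areas = mu.vertex_areas(lmesh.mesh)
    amask = lmesh.vertices_in(Region.ANEURYSM)
    pmask = lmesh.vertices_in(Region.PARENT_ROI)
    wa, wp = areas[amask], areas[pmask]

    awss = time_average_wss(field)
    osi = compute_osi(field)
    awssg = compute_awssg(field)
    mag_sys = np.linalg.norm(field.at_time(field.t_peak_systole), axis=1)
    mag_dia = np.linalg.norm(field.at_time(field.t_end_diastole), axis=1)

    def wmean(x, w):
        return float(np.average(x, weights=w))

    return HemoReport(
        AWSS_A=wmean(awss[amask], wa),
        AWSS_P=wmean(awss[pmask], wp),
        LWSS_A=float(wa[mag_dia[amask] < config.low_wss_threshold].sum() / wa.sum()),
        MWSS_A=float(mag_sys[amask].max()),
        WSS90_A=mu.weighted_percentile(mag_sys[amask], wa, config.wss_percentile),
        OSI_A=wmean(osi[amask], wa),
        MOSI_A=float(osi[amask].max()),
        HOSI_A=float(wa[osi[amask] > config.high_osi_threshold].sum() / wa.sum()),
        AWSSG_A=wmean(awssg[amask], wa),
        provenance=provenance or {},
    )
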