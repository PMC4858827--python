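"""Labeled vascular surface meshes.

A :class:`LabeledSurfaceMesh` couples a watertight triangulated lumen surface
(millimetre coordinates) with a per-face anatomical region label and the neck
curve separating the aneurysm sac from its parent vessel.  STL cannot carry
labels, so meshes are written as STL plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh


class Region(str, Enum):
    ANEURYSM = "aneurysm"
    NECK_BAND = "neck_band"
    PARENT_ROI = "parent_roi"
    EXTENSION = "extension"
    OTHER = "other"


_REGION_CODES = {r: i for i, r in enumerate(Region)}
_CODE_REGIONS = {i: r for r, i in _REGION_CODES.items()}


@dataclass
class LabeledSurfaceMesh:
    """Triangulated vascular surface with per-face region labels.

    Attributes
    ----------
    mesh:
        Watertight trimesh in world millimetres.
    face_region:
        Integer code per face; decode with :meth:`region_of` / ``Region``.
    neck_curve:
        Ordered closed polyline (n, 3) separating sac from parent, or None.
    provenance:
        Free-form metadata (config hashes, seeds, warnings).
    """

    mesh: trimesh.Trimesh
    face_region: np.ndarray
    neck_curve: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.face_region = np.asarray(self.face_region, dtype=np.int8)
        if len(self.face_region) != len(self.mesh.faces):
            raise ValueError("face_region length must match face count")
        if self.neck_curve is not None:
            self.neck_curve = np.asarray(self.neck_curve, dtype=float)

    @staticmethod
    def code(region: Region) -> int:
        return _REGION_CODES[region]

    @staticmethod
    def region_of(code: int) -> Region:
        return _CODE_REGIONS[int(code)]

    def faces_in(self, region: Region) -> np.ndarray:
        """Boolean face mask for one region."""
        return self.face_region == _REGION_CODES[region]

    def vertices_in(self, region: Region) -> np.ndarray:
        """Boolean vertex mask: vertices touching at least one face of region."""
        mask = np.zeros(len(self.mesh.vertices), dtype=bool)
        mask[self.mesh.faces[self.faces_in(region)].ravel()] = True
        return mask

    def region_area(self, region: Region) -> float:
        return float(self.mesh.area_faces[self.faces_in(region)].sum())

    def submesh(self, face_mask: np.ndarray) -> trimesh.Trimesh:
        return self.mesh.submesh([np.nonzero(face_mask)[0]], append=True)

    # ---------------------------------------------------------------- I/O
    def save(self, stl_path, sidecar_path=None) -> None:
        stl_path = Path(stl_path)
        self.mesh.export(stl_path)
        sidecar = Path(sidecar_path) if sidecar_path else stl_path.with_suffix(".labels.json")
        payload = {
            "face_region": self.face_region.astype(int).tolist(),
            "region_codes": {r.value: c for r, c in _REGION_CODES.items()},
            "neck_curve": None if self.neck_curve is None else self.neck_curve.tolist(),
            "provenance": self.provenance,
        }
        sidecar.write_text(json.dumps(payload))

    @classmethod
    def load(cls, stl_path, sidecar_path=None) -> "LabeledSurfaceMesh":
        stl_path = Path(stl_path)
        mesh = trimesh.load_mesh(stl_path, process=False)
        sidecar = Path(sidecar_path) if sidecar_path else stl_path.with_suffix(".labels.json")
        data = json.loads(sidecar.read_text())
        curve = data.get("neck_curve")
        return cls(
            mesh=mesh,
            face_region=np.array(data["face_region"], dtype=np.int8),
            neck_curve=None if curve is None else np.array(curve, float),
            provenance=data.get("provenance", {}),
        )
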