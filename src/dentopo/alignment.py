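"""Canonical orientation of a tooth from three dentine-horn landmarks, and
occlusal region-of-interest extraction.

The reference plane is the plane through the dentine-horn tips at protocone,
paracone and metacone (on the EDJ); it is mapped to the xy plane with the
occlusal relief on the +z side.  The mesial axis (protocone tip -> paracone
tip) is made parallel to +x.  Each mesh is finally shifted so its lowermost
cervix vertex sits at z = 0, crown height reading on a z-positive scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import nearest_on_surface
from .mesh import TriangleMesh

log = logging.getLogger("dentopo")

__all__ = ["LandmarkSet", "RigidTransform", "align_to_landmarks",
           "occlusal_roi", "read_landmarks"]

_COLLINEAR_AREA_TOL = 1e-9  # mm^2
_LANDMARK_SURFACE_TOL = 0.5  # mm, warn beyond this


@dataclass
class LandmarkSet:
    """Dentine-horn tip coordinates (mm) in the mesh frame."""
    protocone_tip: np.ndarray
    paracone_tip: np.ndarray
    metacone_tip: np.ndarray
    basin_point_oes: np.ndarray | None = None
    basin_point_edj: np.ndarray | None = None
    side: str = "left"

    def __post_init__(self):
        for name in ("protocone_tip", "paracone_tip", "metacone_tip",
                     "basin_point_oes", "basin_point_edj"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=np.float64).reshape(3))
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def tips(self) -> np.ndarray:
        return np.stack([self.protocone_tip, self.paracone_tip,
                         self.metacone_tip])

    def tip_triangle_area(self) -> float:
        t = self.tips
        return 0.5 * float(np.linalg.norm(
            np.cross(t[1] - t[0], t[2] - t[0])))


@dataclass
class RigidTransform:
    """Rotation + translation mapping the original frame to the aligned one.

    ``translation`` carries the z offset of the EDJ; ``z_offsets`` records
    the per-mesh vertical shifts that put each surface's own lowermost cervix
    vertex at z = 0 (the two cervices need not coincide).
    """
    rotation: np.ndarray
    translation: np.ndarray
    mirror: bool = False
    z_offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        if self.mirror:
            p = p * np.array([-1.0, 1.0, 1.0])
        return p @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points, dtype=np.float64) - self.translation) @ self.rotation
        if self.mirror:
            p = p * np.array([-1.0, 1.0, 1.0])
        return p

    def is_identity(self, tol: float = 1e-6) -> bool:
        return (not self.mirror
                and np.allclose(self.rotation, np.eye(3), atol=tol)
                and np.allclose(self.translation, 0.0, atol=tol))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "mirror": self.mirror,
            "z_offsets": {k: float(v) for k, v in self.z_offsets.items()},
            "conventions": {
                "x_axis": "protocone tip -> paracone tip (projected)",
                "z_axis": "cervix -> occlusal, tips above crown centroid",
            },
        }, indent=2))


def read_landmarks(path) -> LandmarkSet:
    """Landmark file: JSON mapping names to [x, y, z], or CSV with columns
    name,x,y,z."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such landmark file: {path}")
    if path.suffix.lower() == ".json":
        d = json.loads(path.read_text())
    else:
        import csv
        d = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                d[row["name"]] = [float(row["x"]), float(row["y"]),
                                  float(row["z"])]
            if "side" not in d:
                d.setdefault("side", "left")
    side = d.pop("side", "left")
    try:
        return LandmarkSet(
            protocone_tip=d["protocone_tip"],
            paracone_tip=d["paracone_tip"],
            metacone_tip=d["metacone_tip"],
            basin_point_oes=d.get("basin_point_oes"),
            basin_point_edj=d.get("basin_point_edj"),
            side=side if isinstance(side, str) else "left",
        )
    except KeyError as e:
        raise ValueError(f"landmark file missing point {e}") from e


def _rotation_to_z(n: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector n to +z."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(n, z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def align_to_landmarks(oes: TriangleMesh, edj: TriangleMesh,
                       lm: LandmarkSet):
    """Align an OES/EDJ pair to the canonical frame.

    Returns ``(oes_aligned, edj_aligned, transform)``.  The same rotation and
    in-plane translation are applied to both meshes; each mesh is then
    z-shifted so its own lowermost cervix vertex lies at z = 0 (offsets
    recorded on the transform).
    """
    if lm.tip_triangle_area() < _COLLINEAR_AREA_TOL:
        raise ValueError("dentine-horn tips are collinear; cannot define the "
                         "reference plane")

    mirror = lm.side == "right"
    M = np.array([-1.0, 1.0, 1.0]) if mirror else np.array([1.0, 1.0, 1.0])
    tips = lm.tips * M
    edj_v = edj.vertices * M
    oes_v = oes.vertices * M

    # landmarks should lie on (or very near) the EDJ surface
    d, _, _ = nearest_on_surface(tips, edj_v, edj.faces * 1, k=8, exact=True)
    if np.any(d > _LANDMARK_SURFACE_TOL):
        warnings.warn("landmark(s) farther than %.2f mm from the EDJ surface"
                      % _LANDMARK_SURFACE_TOL)

    n = np.cross(tips[1] - tips[0], tips[2] - tips[0])
    n /= np.linalg.norm(n)
    centroid = edj_v.mean(axis=0)
    # choose the normal sign that puts the tips on the occlusal (+z) side
    # of the crown centroid
    if np.dot(tips.mean(axis=0) - centroid, n) < 0:
        n = -n
    R1 = _rotation_to_z(n)

    # mesial axis: protocone -> paracone parallel to +x
    d_pa = R1 @ (tips[1] - tips[0])
    ang = np.arctan2(d_pa[1], d_pa[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    R = R2 @ R1

    tips_r = tips @ R.T
    t_xy = -tips_r.mean(axis=0)
    t_xy[2] = 0.0

    edj_r = edj_v @ R.T + t_xy
    oes_r = oes_v @ R.T + t_xy
    dz_edj = -float(edj_r[:, 2].min())
    dz_oes = -float(oes_r[:, 2].min())
    edj_r[:, 2] += dz_edj
    oes_r[:, 2] += dz_oes

    tf = RigidTransform(R, t_xy + np.array([0.0, 0.0, dz_edj]), mirror=mirror,
                        z_offsets={"oes": dz_oes, "edj": dz_edj})

    oes_out = oes.copy()
    edj_out = edj.copy()
    oes_out.vertices = oes_r
    edj_out.vertices = edj_r
    if mirror:
        # mirroring flips winding; restore outward normals
        oes_out.faces = oes_out.faces[:, ::-1]
        edj_out.faces = edj_out.faces[:, ::-1]
    return oes_out, edj_out, tf


def occlusal_roi(mesh: TriangleMesh, basin_point=None,
                 z_cut: float | None = None,
                 tips: np.ndarray | None = None) -> np.ndarray:
    """Face mask of the occlusal region: faces whose barycenter lies at or
    above the basin plane (parallel to the reference plane through the
    lowermost basin point).

    The cut height comes from, in order of precedence: ``z_cut``, the z of
    ``basin_point``, or (auto mode, requires ``tips``) the lowest vertex
    inside the 2D convex hull of the three dentine-horn tips projected to xy.
    """
    if z_cut is None:
        if basin_point is not None:
            z_cut = float(np.asarray(basin_point, dtype=np.float64)[2])
        elif tips is not None:
            z_cut = _auto_basin_z(mesh, np.asarray(tips, dtype=np.float64))
        else:
            raise ValueError("need basin_point, z_cut or tips")
    bz = mesh.face_centroids()[:, 2]
    mask = bz >= z_cut
    if not mask.any():
        raise ValueError(f"empty ROI: cut plane z={z_cut:.3f} is above the "
                         "highest face barycenter")
    return mask


def _auto_basin_z(mesh: TriangleMesh, tips: np.ndarray) -> float:
    """Lowest vertex of the mesh whose xy lies strictly inside the triangle
    of the three tip projections."""
    a, b, c = tips[:, :2]
    p = mesh.vertices[:, :2]

    def cross2(o, u, v):
        return (u[0] - o[0]) * (v[:, 1] - o[1]) - (u[1] - o[1]) * (v[:, 0] - o[0])

    s1 = cross2(a, b, p)
    s2 = cross2(b, c, p)
    s3 = cross2(c, a, p)
    inside = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
    if not inside.any():
        raise ValueError("no mesh vertex projects inside the tip triangle")
    return float(mesh.vertices[inside, 2].min())
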