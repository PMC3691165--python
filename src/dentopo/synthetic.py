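"""Synthetic tooth-crown pairs and analytic primitives with known ground
truth.

No specimen meshes accompany the method, so validation relies on generated
surfaces.  Two kinds are provided:

* analytic primitives (plane, sphere, hemisphere, cone, cylinder, concentric
  shells) whose elevation, inclination, orientation, curvature and — for the
  shells — thickness have closed forms;
* multi-cusp crowns: the EDJ is a smooth height field over an elliptical
  footprint (dome + Gaussian cusps − Gaussian basin, tapered to the cervix
  at z = 0) and the OES is the EDJ offset along its vertex normals by a
  controllable thickness field, so the generated enamel thickness is known
  exactly.

Default crown parameters emulate an anthropoid upper second molar: a
~11 x 10 mm four-cusp crown, 2-3 mm of basin-to-cusp relief, 0.6 mm of
occlusal enamel (mid-range for medium-sized anthropoids), and
~22,000-triangle surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .alignment import LandmarkSet
from .mesh import TriangleMesh

log = logging.getLogger("dentopo")

__all__ = ["SyntheticToothSpec", "make_primitive", "make_synthetic_tooth",
           "PrimitiveOracle"]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclass
class PrimitiveOracle:
    """Closed-form signifiers of an analytic primitive, evaluated at surface
    points.  ``phi`` is the mean curvature with the convex-outward-positive
    sign convention; ``delta`` (shells only) the exact inter-shell
    distance."""
    kind: str
    params: dict

    def inclination(self, p: np.ndarray) -> np.ndarray:
        n = self._normal(np.atleast_2d(p))
        return 180.0 - np.degrees(np.arccos(np.clip(n[:, 2], -1, 1)))

    def orientation(self, p: np.ndarray) -> np.ndarray:
        n = self._normal(np.atleast_2d(p))
        psi = np.degrees(np.arctan2(n[:, 1], n[:, 0])) % 360.0
        psi[np.hypot(n[:, 0], n[:, 1]) < 1e-8] = np.nan
        return psi

    def elevation(self, p: np.ndarray) -> np.ndarray:
        return np.atleast_2d(p)[:, 2]

    def phi(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        k = self.kind
        if k == "plane":
            return np.zeros(len(p))
        if k in ("sphere", "hemisphere"):
            return np.full(len(p), 1.0 / self.params["radius"])
        if k == "cylinder":
            return np.full(len(p), 0.5 / self.params["radius"])
        if k == "cone":
            # principal curvatures: 0 along the ruling, cos(alpha)/r around
            alpha = np.radians(self.params["half_angle_deg"])
            r = np.hypot(p[:, 0], p[:, 1])
            with np.errstate(divide="ignore"):
                return 0.5 * np.cos(alpha) / r
        raise NotImplementedError(k)

    @property
    def delta(self) -> float:
        if self.kind != "concentric_shells":
            raise AttributeError("delta is defined for concentric shells only")
        return self.params["r_outer"] - self.params["r_inner"]

    def _normal(self, p: np.ndarray) -> np.ndarray:
        k = self.kind
        if k == "plane":
            return np.tile([0.0, 0.0, 1.0], (len(p), 1))
        if k in ("sphere", "hemisphere", "concentric_shells"):
            c = np.asarray(self.params.get("center", (0, 0, 0)), dtype=float)
            d = p - c
            return d / np.linalg.norm(d, axis=1, keepdims=True)
        if k == "cylinder":
            d = p.copy()
            d[:, 2] = 0
            return d / np.linalg.norm(d, axis=1, keepdims=True)
        if k == "cone":
            alpha = np.radians(self.params["half_angle_deg"])
            az = np.arctan2(p[:, 1], p[:, 0])
            return np.column_stack([np.cos(az) * np.cos(alpha),
                                    np.sin(az) * np.cos(alpha),
                                    np.full(len(p), np.sin(alpha))])
        raise NotImplementedError(k)


def _parametric_grid(rings: int, sectors: int, ring_pts, closed_top=False):
    """Triangulate a (ring, sector) parametric sheet; ``ring_pts(i)`` returns
    the 3D circle of ring i (length = sectors)."""
    verts = []
    for i in range(rings + 1):
        verts.append(ring_pts(i))
    verts = np.concatenate(verts)
    faces = []
    for i in range(rings):
        for j in range(sectors):
            a = i * sectors + j
            b = i * sectors + (j + 1) % sectors
            c = (i + 1) * sectors + j
            d = (i + 1) * sectors + (j + 1) % sectors
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


def make_primitive(kind: str, resolution: int = 4, **params):
    """Analytic test primitive with its closed-form oracle.

    Returns ``(mesh, oracle)``; for ``concentric_shells`` returns
    ``(outer_mesh, inner_mesh, oracle)``.  ``resolution`` scales the mesh
    density (icosphere subdivisions, or ring count for parametric sheets).
    Winding is outward / upward-facing so signifier conventions apply
    directly.
    """
    import trimesh

    if kind == "plane":
        size = params.setdefault("size", 1.0)
        z0 = params.setdefault("z", 0.0)
        n = max(2, resolution * 8)
        xs = np.linspace(-size / 2, size / 2, n)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        tri = Delaunay(pts)
        verts = np.column_stack([pts, np.full(len(pts), z0)])
        return TriangleMesh(verts, _ccw_up(verts, tri.simplices)), \
            PrimitiveOracle(kind, params)

    if kind == "sphere":
        r = params.setdefault("radius", 1.0)
        if r <= 0:
            raise ValueError("radius must be positive")
        m = trimesh.creation.icosphere(subdivisions=resolution, radius=r)
        return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces)), \
            PrimitiveOracle(kind, params)

    if kind == "hemisphere":
        r = params.setdefault("radius", 1.0)
        if r <= 0:
            raise ValueError("radius must be positive")
        rings = max(4, resolution * 8)
        sectors = max(16, resolution * 16)

        def ring_pts(i):
            th = (np.pi / 2) * (1 - i / rings)  # polar angle: rim -> pole
            if i == rings:
                th = 1e-9  # near-pole ring avoids a degenerate fan
            az = 2 * np.pi * np.arange(sectors) / sectors
            return np.column_stack([r * np.sin(th) * np.cos(az),
                                    r * np.sin(th) * np.sin(az),
                                    np.full(sectors, r * np.cos(th))])

        verts, faces = _parametric_grid(rings, sectors, ring_pts)
        return TriangleMesh(verts, faces), PrimitiveOracle(kind, params)

    if kind == "cone":
        alpha = params.setdefault("half_angle_deg", 45.0)
        h = params.setdefault("height", 1.0)
        if h <= 0:
            raise ValueError("height must be positive")
        rb = h * np.tan(np.radians(alpha))
        params["base_radius"] = rb
        rings = max(4, resolution * 8)
        sectors = max(16, resolution * 16)
        if sectors % 8:
            sectors += 8 - sectors % 8  # bin-symmetric azimuthal sampling

        def ring_pts(i):
            f = 1 - i / rings  # 1 at base -> 0 at apex
            f = max(f, 1e-9)
            az = 2 * np.pi * np.arange(sectors) / sectors
            return np.column_stack([rb * f * np.cos(az),
                                    rb * f * np.sin(az),
                                    np.full(sectors, h * (1 - f))])

        verts, faces = _parametric_grid(rings, sectors, ring_pts)
        return TriangleMesh(verts, faces), PrimitiveOracle(kind, params)

    if kind == "cylinder":
        r = params.setdefault("radius", 1.0)
        h = params.setdefault("height", 2.0)
        if r <= 0 or h <= 0:
            raise ValueError("radius and height must be positive")
        rings = max(4, resolution * 8)
        sectors = max(16, resolution * 16)

        def ring_pts(i):
            az = 2 * np.pi * np.arange(sectors) / sectors
            return np.column_stack([r * np.cos(az), r * np.sin(az),
                                    np.full(sectors, h * i / rings)])

        verts, faces = _parametric_grid(rings, sectors, ring_pts)
        return TriangleMesh(verts, faces), PrimitiveOracle(kind, params)

    if kind == "concentric_shells":
        r1 = params.setdefault("r_inner", 5.0)
        r2 = params.setdefault("r_outer", 6.0)
        if not 0 < r1 < r2:
            raise ValueError("need 0 < r_inner < r_outer")
        inner = trimesh.creation.icosphere(subdivisions=resolution, radius=r1)
        outer = trimesh.creation.icosphere(subdivisions=resolution, radius=r2)
        return (TriangleMesh(np.asarray(outer.vertices), np.asarray(outer.faces)),
                TriangleMesh(np.asarray(inner.vertices), np.asarray(inner.faces)),
                PrimitiveOracle(kind, params))

    raise ValueError(f"unknown primitive kind {kind!r}")


def _ccw_up(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip faces whose normal points downward (for height-field meshes)."""
    t = verts[faces]
    cz = ((t[:, 1, 0] - t[:, 0, 0]) * (t[:, 2, 1] - t[:, 0, 1])
          - (t[:, 1, 1] - t[:, 0, 1]) * (t[:, 2, 0] - t[:, 0, 0]))
    out = faces.copy()
    out[cz < 0] = out[cz < 0][:, ::-1]
    return out


# ---------------------------------------------------------------------------
# tooth-like crowns
# ---------------------------------------------------------------------------

_DEFAULT_CUSPS = (
    # (name, x, y, height mm, width mm) — upper-molar layout: mesial at -y,
    # lingual at -x; protocone -> paracone runs roughly along +x... cusp
    # positions chosen so the three landmark tips are far from collinear.
    ("protocone", -2.4, -2.1, 3.0, 1.60),
    ("paracone", 2.5, -2.2, 3.3, 1.55),
    ("metacone", 2.3, 2.2, 3.1, 1.55),
    ("hypocone", -2.2, 2.0, 2.6, 1.70),
)


@dataclass
class SyntheticToothSpec:
    """Parameters of a generated crown.

    ``thickness`` may be a constant (mm) or a callable t(x, y) -> mm.
    ``cusp_sharpness`` scales cusp widths down (sharper) without changing
    heights; ``relief`` scales cusp heights.  ``jitter`` adds seeded Gaussian
    vertex noise (mm) to both surfaces after construction.
    """
    semi_axes: tuple[float, float] = (5.6, 5.2)
    cusps: tuple = _DEFAULT_CUSPS
    dome_height: float = 2.2
    basin_depth: float = 0.8
    basin_width: float = 2.7
    thickness: float | object = 0.6
    target_faces: int = 22000
    relief: float = 1.0
    cusp_sharpness: float = 1.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(c[3] <= 0 or c[4] <= 0 for c in self.cusps):
            raise ValueError("cusp heights and widths must be positive")
        if not callable(self.thickness) and self.thickness < 0:
            raise ValueError("thickness must be non-negative")
        if self.target_faces < 200:
            raise ValueError("target_faces too small")

    def height(self, x, y):
        """EDJ height field (mm) over the footprint: paraboloid dome plus
        Gaussian cusps minus a central Gaussian basin.  All terms are smooth,
        with concave curvature radii large against realistic enamel
        thickness, so the normal-offset OES stays embedded."""
        a, b = self.semi_axes
        rho2 = (x / a) ** 2 + (y / b) ** 2
        z = self.dome_height * np.clip(1.0 - rho2, 0.0, None)
        z = z - self.basin_depth * np.exp(-(x ** 2 + y ** 2)
                                          / (2 * self.basin_width ** 2))
        for _, cx, cy, h, w in self.cusps:
            w = w * self.cusp_sharpness
            z = z + self.relief * h * np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                                             / (2 * w ** 2))
        return z

    def thickness_at(self, x, y):
        if callable(self.thickness):
            return np.asarray(self.thickness(x, y), dtype=np.float64)
        return np.full(np.shape(x), float(self.thickness))


def _footprint_points(spec: SyntheticToothSpec, n_pts: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Near-uniform points in the elliptical footprint: sunflower interior
    plus an explicit boundary ring."""
    a, b = spec.semi_axes
    n_bnd = max(32, int(np.sqrt(n_pts) * 2.2))
    t = 2 * np.pi * np.arange(n_bnd) / n_bnd
    bnd = np.column_stack([a * np.cos(t), b * np.sin(t)])
    n_int = n_pts - n_bnd
    i = np.arange(1, n_int + 1)
    golden = (1 + np.sqrt(5)) / 2
    r = np.sqrt(i / (n_int + 1)) * (1 - 1.2 / np.sqrt(n_int))
    th = 2 * np.pi * i / golden ** 2
    inner = np.column_stack([a * r * np.cos(th), b * r * np.sin(th)])
    return np.vstack([bnd, inner])


def make_synthetic_tooth(spec: SyntheticToothSpec):
    """Generate an (OES, EDJ, landmarks, truth) tuple.

    The EDJ is the triangulated height field; the OES is the EDJ offset
    along its (outward) vertex normals by the thickness field.  Landmarks
    are the apices of the three tallest named cusps.  ``truth`` records the
    requested thickness field, actual cusp apex heights and the basin z.

    Raises if the offset folds the surface over (thickness too large for
    the EDJ curvature).
    """
    rng = np.random.default_rng(spec.seed)
    n_pts = max(200, spec.target_faces // 2 + int(np.sqrt(spec.target_faces)))
    pts = _footprint_points(spec, n_pts, rng)
    tri = Delaunay(pts)
    faces = np.asarray(tri.simplices, dtype=np.int64)
    z = spec.height(pts[:, 0], pts[:, 1])
    verts = np.column_stack([pts, z])
    faces = _ccw_up(verts, faces)
    # drop boundary slivers
    t = verts[faces]
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0],
                                          t[:, 2] - t[:, 0]), axis=1)
    faces = faces[areas > 1e-10]
    edj = TriangleMesh(verts, faces)

    # OES: offset along EDJ vertex normals
    fc = edj.face_cross()
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fc)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vn /= norms
    t_v = spec.thickness_at(verts[:, 0], verts[:, 1])
    oes_verts = verts + vn * t_v[:, None]
    oes = TriangleMesh(oes_verts, faces.copy())

    # offset validity: no face may flip against its EDJ counterpart
    if float(np.max(t_v)) > 0:
        dots = np.einsum("ij,ij->i", oes.face_cross(), edj.face_cross())
        if (dots <= 0).any():
            raise ValueError("thickness too large for curvature: offset "
                             "surface folds over")

    if spec.jitter > 0:
        edj.vertices = edj.vertices + rng.normal(0, spec.jitter,
                                                 edj.vertices.shape)
        oes.vertices = oes.vertices + rng.normal(0, spec.jitter,
                                                 oes.vertices.shape)

    # landmarks: apex vertex of each named cusp (highest z within one width)
    tips = {}
    for name, cx, cy, h, w in spec.cusps:
        d2 = (verts[:, 0] - cx) ** 2 + (verts[:, 1] - cy) ** 2
        near = d2 < (1.5 * w) ** 2
        if not near.any():
            raise ValueError(f"cusp {name} has no mesh vertices nearby")
        idx = np.where(near)[0][np.argmax(edj.vertices[near, 2])]
        tips[name] = edj.vertices[idx].copy()
    for required in ("protocone", "paracone", "metacone"):
        if required not in tips:
            raise ValueError(f"spec lacks a {required} cusp")
    lm = LandmarkSet(protocone_tip=tips["protocone"],
                     paracone_tip=tips["paracone"],
                     metacone_tip=tips["metacone"])

    # truth: basin = lowest vertex inside the tip triangle (xy)
    tri_tips = np.stack([tips["protocone"], tips["paracone"],
                         tips["metacone"]])
    a, b, c = tri_tips[:, :2]
    p2 = edj.vertices[:, :2]

    def _cross2(o, u):
        return ((u[0] - o[0]) * (p2[:, 1] - o[1])
                - (u[1] - o[1]) * (p2[:, 0] - o[0]))

    s1, s2, s3 = _cross2(a, b), _cross2(b, c), _cross2(c, a)
    inside = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | \
             ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
    basin_idx = np.where(inside)[0][np.argmin(edj.vertices[inside, 2])]
    truth = {
        "thickness_constant": (None if callable(spec.thickness)
                               else float(spec.thickness)),
        "cusp_apices": {k: v.tolist() for k, v in tips.items()},
        "basin_point_edj": edj.vertices[basin_idx].tolist(),
        "basin_z_edj": float(edj.vertices[basin_idx, 2]),
        "seed": spec.seed,
    }
    log.info("synthetic tooth: %d EDJ faces, %d OES faces", edj.n_faces,
             oes.n_faces)
    return oes, edj, lm, truth
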