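"""Per-polygon topographic signifiers.

For every face of an aligned surface: area (upsilon), barycenter (chi),
elevation (gamma = barycenter z), unit outward normal, orientation (psi, the
azimuth of the normal in the xy plane on 0-360 deg), inclination (lambda, on
0-180 deg: 180 horizontal up-facing, 90 vertical, < 90 re-entrant), signed
mean curvature (phi, 1/mm, convex toward the outward normal positive) and
size-standardized curvature (phi_std).

The signifier table is a pandas DataFrame with one row per face; columns::

    area  cx  cy  cz  elevation  nx  ny  nz  degenerate
    orientation  orientation_defined  inclination
    mean_curvature  curvature_boundary  [phi_std]
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix

from .mesh import DEGENERATE_AREA, TriangleMesh

log = logging.getLogger("dentopo")

HORIZONTAL_TOL = 1e-8  # hypot(nx, ny) below this -> orientation undefined

__all__ = ["face_geometry", "orientation", "inclination", "mean_curvature",
           "standardize_curvature", "compute_signifiers", "enclosed_volume"]


def face_geometry(mesh: TriangleMesh) -> pd.DataFrame:
    """Area, barycenter, elevation and unit normal per face; degenerate
    faces (area below tolerance) flagged for downstream exclusion."""
    areas = mesh.face_areas()
    cent = mesh.face_centroids()
    normals = mesh.face_normals()
    return pd.DataFrame({
        "area": areas,
        "cx": cent[:, 0], "cy": cent[:, 1], "cz": cent[:, 2],
        "elevation": cent[:, 2],
        "nx": normals[:, 0], "ny": normals[:, 1], "nz": normals[:, 2],
        "degenerate": areas < DEGENERATE_AREA,
    })


def orientation(normals: np.ndarray) -> np.ndarray:
    """Azimuth of the normal in the xy plane, counter-clockwise from +x
    (viewed from +z), in [0, 360).  NaN where the normal is (anti)parallel
    to z (horizontal face: direction undefined)."""
    arr = np.asarray(normals, dtype=np.float64)
    n = np.atleast_2d(arr)
    h = np.hypot(n[:, 0], n[:, 1])
    psi = np.degrees(np.arctan2(n[:, 1], n[:, 0])) % 360.0
    psi[h < HORIZONTAL_TOL] = np.nan
    return float(psi[0]) if arr.ndim == 1 else psi


def inclination(normals: np.ndarray) -> np.ndarray:
    """Inclination in degrees: 180 - angle(normal, +z).

    180 for horizontal up-facing polygons, 90 for vertical ones, below 90
    for re-entrant (overhanging) surfaces, 0 for horizontal down-facing."""
    arr = np.asarray(normals, dtype=np.float64)
    n = np.atleast_2d(arr)
    nz = np.clip(n[:, 2], -1.0, 1.0)
    lam = 180.0 - np.degrees(np.arccos(nz))
    return float(lam[0]) if arr.ndim == 1 else lam


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    fc = mesh.face_cross()  # area-weighted normals
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fc)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def _two_ring(mesh: TriangleMesh):
    """CSR adjacency whose rows are the 2-ring neighborhoods."""
    n = mesh.n_vertices
    e = mesh.edges(unique=True)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A2 = (A + A @ A).tocsr()
    A2.setdiag(0)
    A2.eliminate_zeros()
    return A2


def mean_curvature(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Signed mean curvature per face (mean of the two principal normal
    curvatures), with a boundary flag.

    Estimated by a per-vertex least-squares quadric fit over the 2-ring
    neighborhood in the local tangent frame; the face value is the mean of
    its three vertex values.  Sign convention: convex toward the outward
    normal is positive (sphere of radius R with outward normals -> +1/R),
    concave negative, flat ~ 0.  Faces with a vertex on an open boundary are
    flagged (one-sided neighborhoods make the fit unreliable there).

    Returns ``(phi_per_face, boundary_flag_per_face)``.
    """
    V = mesh.vertices
    vn = _vertex_normals(mesh)
    ring = _two_ring(mesh)
    indptr, indices = ring.indptr, ring.indices

    phi_v = np.zeros(mesh.n_vertices)
    # local frame per vertex
    ref = np.where(np.abs(vn[:, 0:1]) < 0.9,
                   np.tile([1.0, 0.0, 0.0], (len(V), 1)),
                   np.tile([0.0, 1.0, 0.0], (len(V), 1)))
    t1 = np.cross(vn, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(vn, t1)

    for v in range(mesh.n_vertices):
        nb = indices[indptr[v]:indptr[v + 1]]
        if len(nb) < 5:
            continue
        d = V[nb] - V[v]
        x = d @ t1[v]
        y = d @ t2[v]
        z = d @ vn[v]
        M = np.column_stack([x * x, x * y, y * y, x, y])
        coef, *_ = np.linalg.lstsq(M, z, rcond=None)
        a, b, c, dd, ee = coef
        denom = (1.0 + dd * dd + ee * ee) ** 1.5
        h_graph = ((1 + ee * ee) * 2 * a - 2 * dd * ee * b
                   + (1 + dd * dd) * 2 * c) / (2 * denom)
        # graph frame has +z = outward normal; convex-outward means the
        # surface bends away from the normal (negative graph curvature)
        phi_v[v] = -h_graph

    phi_f = phi_v[mesh.faces].mean(axis=1)
    bmask = mesh.boundary_vertices()
    boundary_f = bmask[mesh.faces].any(axis=1)
    return phi_f, boundary_f


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume enclosed between the aligned surface and the base plane z = 0
    (divergence theorem with F = (0, 0, z): vertical closure walls and the
    base contribute nothing)."""
    t = mesh.triangles
    cross_z = ((t[:, 1, 0] - t[:, 0, 0]) * (t[:, 2, 1] - t[:, 0, 1])
               - (t[:, 1, 1] - t[:, 0, 1]) * (t[:, 2, 0] - t[:, 0, 0]))
    signed_proj = 0.5 * cross_z
    zmean = t[:, :, 2].mean(axis=1)
    vol = float((signed_proj * zmean).sum())
    if vol < 0:
        raise ValueError("negative enclosed volume; is the mesh aligned with "
                         "outward normals and z >= 0?")
    return vol


def standardize_curvature(phi: np.ndarray, mesh: TriangleMesh,
                          reference_volume: float | None = None) -> np.ndarray:
    """Size-standardized curvature: phi * (V^(1/3) / V_ref^(1/3)) with V the
    volume of the surface closed against its base plane.  With the mesh
    itself as reference (``reference_volume=None``) this is the identity."""
    v = enclosed_volume(mesh)
    if reference_volume is None:
        reference_volume = v
    if reference_volume <= 0:
        raise ValueError("reference volume must be positive")
    return np.asarray(phi) * (v / reference_volume) ** (1.0 / 3.0)


def compute_signifiers(mesh: TriangleMesh,
                       reference_volume: float | None = None,
                       with_curvature: bool = True) -> pd.DataFrame:
    """Full signifier table for one aligned surface."""
    df = face_geometry(mesh)
    normals = df[["nx", "ny", "nz"]].to_numpy()
    psi = orientation(normals)
    df["orientation"] = psi
    df["orientation_defined"] = ~np.isnan(psi)
    df["inclination"] = inclination(normals)
    if with_curvature:
        phi, bnd = mean_curvature(mesh)
        df["mean_curvature"] = phi
        df["curvature_boundary"] = bnd
        df["phi_std"] = standardize_curvature(phi, mesh, reference_volume)
    return df
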