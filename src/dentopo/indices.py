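"""Derived scalar indices and binned area profiles for OES, EDJ and pairs.

Scalar indices (Table-1 style):

* delta_mean / delta_sd — area-weighted occlusal enamel thickness (mm);
* delta_st — standard occlusal minimum enamel thickness: sum(delta_i *
  area_i) over the OES occlusal faces, divided by the EDJ occlusal 3D area;
* Gamma — occlusal relief index: sum(area * elevation) over faces steeper
  than the 135-degree inclination threshold is the *denominator* sense of
  "steep"; precisely Gamma = sum(area*elev | lambda > T) / sum(area*elev |
  lambda < T) (flat-to-steep, faces exactly at T excluded);
* RI_classic — classic relief index: 3D area over the area of the occlusal
  projection (union of projected triangles, no double counting);
* phi_p — relative crest area: fraction of area with standardized curvature
  above the crest threshold;
* phi_mci — maximum convexity index: sum(area * phi_std | phi_std > 0) /
  total area;
* phi_bi — blunting index: phi_p(EDJ) / phi_p(OES);
* psi_c_ratio — relative complexity: patch count OES / patch count EDJ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .mesh import TriangleMesh

log = logging.getLogger("dentopo")

__all__ = [
    "Profile", "IndexReport", "thickness_stats", "relief_index",
    "classic_relief_index", "binned_area_profile", "curvature_indices",
    "blunting_index", "relative_complexity", "crest_threshold_rule",
]


@dataclass
class Profile:
    """Binned area distribution of one per-face variable."""
    variable: str
    edges: np.ndarray
    area: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variable,
            "lo": self.edges[:-1], "hi": self.edges[1:],
            "area": self.area, "fraction": self.fraction,
        })


@dataclass
class IndexReport:
    """Scalar index set for one surface or one OES/EDJ pair."""
    surface: str
    delta_mean: float | None = None
    delta_sd: float | None = None
    delta_st: float | None = None
    gamma: float | None = None          # occlusal relief index
    ri_classic: float | None = None
    psi_c: int | None = None
    phi_p: float | None = None
    phi_mci: float | None = None
    phi_bi: float | None = None
    psi_c_ratio: float | None = None
    relief_accentuation: float | None = None
    scale_free_thickness: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d.update(self.extras)
        return d


def thickness_stats(face_delta: np.ndarray, face_area: np.ndarray,
                    edj_roi_area: float) -> tuple[float, float, float]:
    """Area-weighted delta mean and sd, and the standard occlusal minimum
    enamel thickness delta_st = sum(delta_i * area_i) / A_EDJ."""
    a = np.asarray(face_area, dtype=np.float64)
    d = np.asarray(face_delta, dtype=np.float64)
    if edj_roi_area <= 0:
        raise ValueError("EDJ ROI area must be positive")
    if a.sum() <= 0:
        raise ValueError("zero OES ROI area")
    w = a / a.sum()
    mean = float(np.sum(w * d))
    sd = float(np.sqrt(np.sum(w * (d - mean) ** 2)))
    d_st = float(np.sum(d * a) / edj_roi_area)
    return mean, sd, d_st


def relief_index(area: np.ndarray, elevation: np.ndarray,
                 lam: np.ndarray, threshold: float = 135.0) -> float:
    """Occlusal relief index Gamma = sum(area*elev | lambda > T) /
    sum(area*elev | lambda < T); faces exactly at T are excluded."""
    area = np.asarray(area, dtype=np.float64)
    elevation = np.asarray(elevation, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    flat = lam > threshold
    steep = lam < threshold
    denom = float(np.sum(area[steep] * elevation[steep]))
    if denom <= 0:
        raise ValueError("no steep faces below the inclination threshold; "
                         "relief index undefined")
    num = float(np.sum(area[flat] * elevation[flat]))
    return num / denom


def classic_relief_index(mesh: TriangleMesh, roi: np.ndarray) -> float:
    """Classic relief index: 3D area of the ROI over the area of its
    projection onto the occlusal plane z = 0 (union of projected triangles,
    overlaps counted once)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    a3d = float(mesh.face_areas()[roi].sum())
    tri2d = mesh.triangles[roi][:, :, :2]
    # drop degenerate projections (vertical faces project to segments)
    cx = ((tri2d[:, 1, 0] - tri2d[:, 0, 0]) * (tri2d[:, 2, 1] - tri2d[:, 0, 1])
          - (tri2d[:, 1, 1] - tri2d[:, 0, 1]) * (tri2d[:, 2, 0] - tri2d[:, 0, 0]))
    keep = np.abs(cx) > 1e-14
    if not keep.any():
        raise ValueError("ROI projection is degenerate")
    polys = shapely.polygons(tri2d[keep])
    union = shapely.union_all(shapely.make_valid(polys))
    a2d = float(union.area)
    if a2d <= 0:
        raise ValueError("ROI projection is degenerate")
    return a3d / a2d


def binned_area_profile(values: np.ndarray, area: np.ndarray,
                        vrange: tuple[float, float], width: float,
                        variable: str = "") -> Profile:
    """Per-bin area = sum of face areas falling in each half-open interval;
    fractions normalized over the binned faces.  NaN values are excluded."""
    lo, hi = vrange
    n = (hi - lo) / width
    if width <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("width must divide the range")
    n = int(round(n))
    v = np.asarray(values, dtype=np.float64)
    a = np.asarray(area, dtype=np.float64)
    ok = np.isfinite(v)
    edges = lo + width * np.arange(n + 1)
    idx = np.clip(((v[ok] - lo) // width).astype(np.int64), 0, n - 1)
    area_b = np.zeros(n)
    np.add.at(area_b, idx, a[ok])
    tot = area_b.sum()
    frac = area_b / tot if tot > 0 else area_b
    return Profile(variable=variable, edges=edges, area=area_b, fraction=frac)


def crest_threshold_rule(phi_std_reference: np.ndarray,
                         quantile: float = 0.9) -> float:
    """Crest threshold: the given quantile (default 90th percentile) of the
    positive standardized curvature values of the reference surface."""
    pos = np.asarray(phi_std_reference, dtype=np.float64)
    pos = pos[np.isfinite(pos) & (pos > 0)]
    if len(pos) == 0:
        return np.inf
    return float(np.quantile(pos, quantile))


def curvature_indices(area: np.ndarray, phi_std: np.ndarray,
                      crest_threshold: float) -> tuple[float, float]:
    """(phi_p, phi_mci): relative crest area and maximum convexity index."""
    a = np.asarray(area, dtype=np.float64)
    p = np.asarray(phi_std, dtype=np.float64)
    ok = np.isfinite(p)
    a, p = a[ok], p[ok]
    tot = a.sum()
    if tot <= 0:
        return 0.0, 0.0
    phi_p = float(a[p > crest_threshold].sum() / tot)
    conv = p > 0
    phi_mci = float(np.sum(a[conv] * p[conv]) / tot)
    return phi_p, phi_mci


def blunting_index(phi_p_edj: float, phi_p_oes: float) -> float:
    """phi_bi = phi_p(EDJ) / phi_p(OES); > 1 means the enamel cap blunts the
    junction's sharp relief.  Both crest areas must use the same threshold."""
    if phi_p_oes <= 0:
        raise ValueError("OES relative crest area is zero; blunting index "
                         "undefined")
    return float(phi_p_edj) / float(phi_p_oes)


def relative_complexity(psi_c_oes: int, psi_c_edj: int) -> float:
    """psi^c-e/d = OES patch count / EDJ patch count."""
    if psi_c_edj <= 0:
        raise ValueError("EDJ complexity is zero; relative complexity "
                         "undefined")
    return float(psi_c_oes) / float(psi_c_edj)
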