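"""Orientation binning, contiguous-patch identification and complexity.

Faces are grouped into orientation intervals (default eight 45-degree bins);
maximal edge-connected runs of same-bin faces form patches; the complexity
(psi^c) is the number of retained patches (size >= ``min_patch_size``, 3 by
default), per bin and in total.  Patch counts are resolution- and
threshold-dependent, so both parameters travel with every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import TriangleMesh

log = logging.getLogger("dentopo")

__all__ = ["PatchSet", "bin_orientation", "find_patches",
           "complexity_summary", "face_adjacency_pairs"]

UNBINNED = -1


@dataclass
class PatchSet:
    """Patches of one surface: per-face patch id (-1 where no retained patch)
    and a per-patch table (patch_id, bin, n_faces, area)."""
    face_patch_id: np.ndarray
    patches: pd.DataFrame
    bin_width: float
    min_patch_size: int
    n_bins: int

    @property
    def total_count(self) -> int:
        return len(self.patches)

    def count_per_bin(self) -> np.ndarray:
        counts = np.zeros(self.n_bins, dtype=np.int64)
        for b, c in self.patches.groupby("bin").size().items():
            counts[int(b)] = c
        return counts

    def area_per_bin(self) -> np.ndarray:
        areas = np.zeros(self.n_bins)
        for b, a in self.patches.groupby("bin")["area"].sum().items():
            areas[int(b)] = a
        return areas


def bin_orientation(psi: np.ndarray, bin_width: float = 45.0) -> np.ndarray:
    """Half-open orientation bins [k*w, (k+1)*w); NaN (undefined, horizontal
    faces) are left unbinned (-1)."""
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-12:
        raise ValueError("bin_width must divide 360")
    psi = np.asarray(psi, dtype=np.float64)
    labels = np.full(psi.shape, UNBINNED, dtype=np.int64)
    ok = np.isfinite(psi)
    n_bins = int(round(360.0 / bin_width))
    labels[ok] = np.minimum((psi[ok] // bin_width).astype(np.int64), n_bins - 1)
    return labels


def face_adjacency_pairs(mesh: TriangleMesh) -> np.ndarray:
    """(k, 2) pairs of face indices sharing an edge (edge adjacency, not
    vertex adjacency)."""
    F = mesh.faces
    e = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    se = np.sort(e, axis=1)
    face_idx = np.tile(np.arange(len(F)), 3)
    order = np.lexsort((se[:, 1], se[:, 0]))
    se_s, f_s = se[order], face_idx[order]
    same = np.all(se_s[1:] == se_s[:-1], axis=1)
    pairs = np.column_stack([f_s[:-1][same], f_s[1:][same]])
    return pairs


def find_patches(mesh: TriangleMesh, labels: np.ndarray,
                 min_patch_size: int = 3,
                 bin_width: float = 45.0) -> PatchSet:
    """Maximal edge-connected components of same-bin faces; components with
    fewer than ``min_patch_size`` faces are discarded (retained inclusively:
    size >= min_patch_size)."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != mesh.n_faces:
        raise ValueError("labels length must equal the face count")
    m = mesh.n_faces
    pairs = face_adjacency_pairs(mesh)
    same = (labels[pairs[:, 0]] == labels[pairs[:, 1]]) & \
           (labels[pairs[:, 0]] != UNBINNED)
    pr = pairs[same]
    g = coo_matrix((np.ones(len(pr)), (pr[:, 0], pr[:, 1])), shape=(m, m))
    _, comp = connected_components(g, directed=False)
    comp = comp.copy()
    comp[labels == UNBINNED] = -1

    areas = mesh.face_areas()
    face_patch = np.full(m, -1, dtype=np.int64)
    rows = []
    pid = 0
    valid = comp >= 0
    if valid.any():
        order = np.argsort(comp[valid], kind="stable")
        fidx = np.where(valid)[0][order]
        cvals = comp[fidx]
        starts = np.searchsorted(cvals, np.unique(cvals))
        bounds = np.append(starts, len(cvals))
        for s0, e0 in zip(bounds[:-1], bounds[1:]):
            members = fidx[s0:e0]
            if len(members) < min_patch_size:
                continue
            face_patch[members] = pid
            rows.append({"patch_id": pid,
                         "bin": int(labels[members[0]]),
                         "n_faces": int(len(members)),
                         "area": float(areas[members].sum())})
            pid += 1
    patches = pd.DataFrame(rows, columns=["patch_id", "bin", "n_faces", "area"])
    n_bins = int(round(360.0 / bin_width))
    return PatchSet(face_patch_id=face_patch, patches=patches,
                    bin_width=bin_width, min_patch_size=min_patch_size,
                    n_bins=n_bins)


def complexity_summary(patchset: PatchSet) -> pd.DataFrame:
    """Per-bin patch counts and areas plus the total row."""
    counts = patchset.count_per_bin()
    areas = patchset.area_per_bin()
    rows = [{"bin": b,
             "lo_deg": b * patchset.bin_width,
             "hi_deg": (b + 1) * patchset.bin_width,
             "psi_c": int(counts[b]),
             "patch_area": float(areas[b])}
            for b in range(patchset.n_bins)]
    rows.append({"bin": -1, "lo_deg": 0.0, "hi_deg": 360.0,
                 "psi_c": int(counts.sum()),
                 "patch_area": float(areas.sum())})
    return pd.DataFrame(rows)
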