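"""Minimum-distance enamel thickness and the OES <-> EDJ correspondence.

Enamel thickness (delta) at each OES node is the minimum Euclidean distance
from the node to the nearest EDJ triangle, exactly (accelerated by a spatial
index but identical in value to an exhaustive all-triangles scan).  The
matched EDJ triangle index is stored per node, and per face: each OES face
is associated with the EDJ face nearest to its barycenter, forming the
correspondence matrix that later pairs OES and EDJ signifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import _SurfaceProximity
from .mesh import DEGENERATE_AREA, TriangleMesh

log = logging.getLogger("dentopo")

__all__ = ["ThicknessField", "thickness_field"]


@dataclass
class ThicknessField:
    """Per-vertex and per-face enamel thickness with EDJ matches.

    ``vertex_delta[i]`` is the exact minimum distance (mm) from OES vertex i
    to the EDJ; ``vertex_match[i]`` the index of the nearest EDJ triangle
    (in the original EDJ face numbering).  ``face_delta`` is the mean of the
    three vertex values; ``face_match`` the EDJ face nearest to the OES face
    barycenter.
    """
    vertex_delta: np.ndarray
    vertex_match: np.ndarray
    face_delta: np.ndarray
    face_match: np.ndarray

    def correspondence_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "oes_face_id": np.arange(len(self.face_delta)),
            "edj_face_id": self.face_match,
            "delta_mm": self.face_delta,
        })


def thickness_field(oes: TriangleMesh, edj: TriangleMesh) -> ThicknessField:
    """Exact minimum-distance enamel thickness field of an aligned pair.

    Degenerate EDJ triangles are excluded from the query (with a warning);
    matches are reported in the original EDJ face numbering.
    """
    if edj.n_faces == 0:
        raise ValueError("EDJ mesh is empty")
    areas = edj.face_areas()
    good = areas >= DEGENERATE_AREA
    if not good.all():
        warnings.warn(f"{int((~good).sum())} degenerate EDJ triangles "
                      "excluded from thickness query")
    if not good.any():
        raise ValueError("EDJ mesh has no non-degenerate triangles")
    faces = edj.faces[good]
    orig_idx = np.where(good)[0]

    prox = _SurfaceProximity(edj.vertices, faces)
    v_delta, v_match, _ = prox.query(oes.vertices, k=16, exact=True)
    f_delta = v_delta[oes.faces].mean(axis=1)
    b_delta, b_match, _ = prox.query(oes.face_centroids(), k=16, exact=True)
    del b_delta
    log.info("thickness: %d OES vertices vs %d EDJ faces, delta "
             "%.3f +/- %.3f mm", oes.n_vertices, len(faces),
             float(v_delta.mean()), float(v_delta.std()))
    return ThicknessField(vertex_delta=v_delta,
                          vertex_match=orig_idx[v_match],
                          face_delta=f_delta,
                          face_match=orig_idx[b_match])
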