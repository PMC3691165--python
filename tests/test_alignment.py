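"""Landmark alignment and occlusal ROI."""

import numpy as np
import pytest

from dentopo import (LandmarkSet, align_to_landmarks, compute_signifiers,
                     occlusal_roi)
from dentopo.synthetic import make_primitive

from conftest import random_rigid


def test_alignment_constraints_hold(small_tooth):
    oes, edj, lm, _ = small_tooth
    o2, e2, tf = align_to_landmarks(oes, edj, lm)
    tips = tf.apply(lm.tips)
    # (a) tips coplanar with the xy plane
    assert np.ptp(tips[:, 2]) < 1e-6
    # (b) protocone -> paracone parallel to +x
    d = tips[1] - tips[0]
    assert abs(np.arctan2(d[1], d[0])) < 1e-6
    assert d[0] > 0
    # (c) occlusal side up: tips above the crown centroid (the transform
    # already carries the EDJ z offset)
    assert tips[0, 2] > e2.vertices[:, 2].mean()
    # (d) each mesh zeroed at its own lowest vertex
    assert abs(o2.vertices[:, 2].min()) < 1e-9
    assert abs(e2.vertices[:, 2].min()) < 1e-9


def test_alignment_idempotent(small_tooth):
    oes, edj, lm, _ = small_tooth
    o2, e2, tf = align_to_landmarks(oes, edj, lm)
    # the transform (EDJ frame) carries the landmarks with their surface
    lm2 = LandmarkSet(protocone_tip=tf.apply(lm.protocone_tip),
                      paracone_tip=tf.apply(lm.paracone_tip),
                      metacone_tip=tf.apply(lm.metacone_tip))
    o3, e3, tf2 = align_to_landmarks(o2, e2, lm2)
    assert np.allclose(tf2.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(o3.vertices, o2.vertices, atol=1e-6)
    assert np.allclose(e3.vertices, e2.vertices, atol=1e-6)


def test_rigid_round_trip_preserves_signifiers(small_tooth):
    """Applying a random rigid motion and realigning leaves every per-face
    signifier unchanged (area/curvature exactly; angles through the frame)."""
    oes, edj, lm, _ = small_tooth
    o_ref, e_ref, _ = align_to_landmarks(oes, edj, lm)
    sig_ref = compute_signifiers(e_ref, with_curvature=False)

    R, t = random_rigid(3)
    oes_m = oes.copy()
    edj_m = edj.copy()
    oes_m.vertices = oes.vertices @ R.T + t
    edj_m.vertices = edj.vertices @ R.T + t
    lm_m = LandmarkSet(protocone_tip=R @ lm.protocone_tip + t,
                       paracone_tip=R @ lm.paracone_tip + t,
                       metacone_tip=R @ lm.metacone_tip + t)
    o_re, e_re, _ = align_to_landmarks(oes_m, edj_m, lm_m)
    sig_re = compute_signifiers(e_re, with_curvature=False)

    assert np.allclose(e_re.vertices, e_ref.vertices, atol=1e-6)
    for col in ("area", "elevation", "inclination"):
        assert np.allclose(sig_re[col], sig_ref[col], atol=1e-6), col
    both = sig_ref["orientation_defined"] & sig_re["orientation_defined"]
    dpsi = (sig_re.loc[both, "orientation"]
            - sig_ref.loc[both, "orientation"]) % 360.0
    dpsi = np.minimum(dpsi, 360.0 - dpsi)
    assert dpsi.max() < 1e-5


def test_collinear_tips_rejected(small_tooth):
    oes, edj, _, _ = small_tooth
    lm = LandmarkSet(protocone_tip=[0, 0, 0], paracone_tip=[1, 0, 0],
                     metacone_tip=[2, 0, 0])
    with pytest.raises(ValueError, match="collinear"):
        align_to_landmarks(oes, edj, lm)


def test_mirrored_right_side_aligns_like_left(small_tooth):
    oes, edj, lm, _ = small_tooth
    o_l, e_l, _ = align_to_landmarks(oes, edj, lm)
    # fabricate the right-side antimere by mirroring the input in x
    M = np.array([-1.0, 1.0, 1.0])
    oes_r = oes.copy()
    edj_r = edj.copy()
    oes_r.vertices = oes.vertices * M
    oes_r.faces = oes.faces[:, ::-1]
    edj_r.vertices = edj.vertices * M
    edj_r.faces = edj.faces[:, ::-1]
    lm_r = LandmarkSet(protocone_tip=lm.protocone_tip * M,
                       paracone_tip=lm.paracone_tip * M,
                       metacone_tip=lm.metacone_tip * M, side="right")
    o_r, e_r, tf = align_to_landmarks(oes_r, edj_r, lm_r)
    assert tf.mirror
    assert np.allclose(e_r.vertices, e_l.vertices, atol=1e-6)


class TestOcclusalROI:
    def test_zero_cut_selects_everything(self, small_tooth):
        oes, edj, lm, _ = small_tooth
        _, e2, _ = align_to_landmarks(oes, edj, lm)
        assert occlusal_roi(e2, z_cut=0.0).all()

    def test_cut_above_apex_raises(self, small_tooth):
        oes, edj, lm, _ = small_tooth
        _, e2, _ = align_to_landmarks(oes, edj, lm)
        with pytest.raises(ValueError, match="empty ROI"):
            occlusal_roi(e2, z_cut=1e3)

    def test_monotone_in_cut_height(self, small_tooth):
        oes, edj, lm, _ = small_tooth
        _, e2, _ = align_to_landmarks(oes, edj, lm)
        area = e2.face_areas()
        cuts = np.linspace(0, e2.vertices[:, 2].max() * 0.8, 8)
        rois = [area[occlusal_roi(e2, z_cut=c)].sum() for c in cuts]
        assert all(a >= b - 1e-12 for a, b in zip(rois, rois[1:]))

    def test_spherical_cap_area_matches_closed_form(self):
        """On a hemisphere, the ROI above z = h has area 2*pi*R*(R - h)."""
        mesh, _ = make_primitive("hemisphere", resolution=5, radius=4.0)
        h = 2.0
        roi = occlusal_roi(mesh, z_cut=h)
        cap = mesh.face_areas()[roi].sum()
        expect = 2 * np.pi * 4.0 * (4.0 - h)
        assert abs(cap / expect - 1.0) < 0.02
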