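"""Derived indices and binned profiles."""

import numpy as np
import pytest

from dentopo import (binned_area_profile, blunting_index,
                     classic_relief_index, compute_signifiers,
                     curvature_indices, mean_curvature, occlusal_roi,
                     relative_complexity, relief_index, thickness_field,
                     thickness_stats)
from dentopo.synthetic import (SyntheticToothSpec, make_primitive,
                               make_synthetic_tooth)


class TestThicknessStats:
    def test_arithmetic(self):
        mean, sd, d_st = thickness_stats(np.array([1.0, 2.0]),
                                         np.array([2.0, 1.0]), 2.0)
        assert np.isclose(mean, 4.0 / 3.0)
        assert np.isclose(d_st, 2.0)

    def test_uniform_identity(self):
        a = np.array([0.3, 0.6, 0.1])
        mean, sd, d_st = thickness_stats(np.full(3, 0.7), a, a.sum())
        assert np.isclose(mean, 0.7)
        assert np.isclose(d_st, 0.7)
        assert np.isclose(sd, 0.0)

    def test_shells_delta_st_exceeds_mean_by_area_ratio(self):
        """delta_st divides by the (smaller) EDJ area: on concentric shells
        the ratio is the squared radius ratio."""
        oes, edj, oracle = make_primitive("concentric_shells", resolution=3,
                                          r_inner=5.0, r_outer=6.0)
        tf = thickness_field(oes, edj)
        mean, _, d_st = thickness_stats(tf.face_delta, oes.face_areas(),
                                        edj.total_area())
        assert abs(d_st / mean - (6.0 / 5.0) ** 2) < 0.01

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            thickness_stats(np.array([1.0]), np.array([1.0]), 0.0)


class TestReliefIndex:
    def test_arithmetic(self):
        gam = relief_index(area=np.array([2.0, 1.0]),
                           elevation=np.array([1.0, 1.0]),
                           lam=np.array([160.0, 120.0]))
        assert np.isclose(gam, 2.0)

    def test_all_flat_raises(self):
        with pytest.raises(ValueError, match="steep"):
            relief_index(np.ones(3), np.ones(3),
                         np.array([150.0, 160.0, 170.0]))

    def test_threshold_faces_excluded(self):
        gam = relief_index(np.array([2.0, 1.0, 5.0]), np.ones(3),
                           np.array([160.0, 120.0, 135.0]))
        assert np.isclose(gam, 2.0)

    def test_matches_independent_summation(self, small_tooth):
        oes, edj, lm, _ = small_tooth
        from dentopo import align_to_landmarks
        _, e2, _ = align_to_landmarks(oes, edj, lm)
        sig = compute_signifiers(e2, with_curvature=False)
        gam = relief_index(sig["area"], sig["elevation"], sig["inclination"])
        a = sig["area"].to_numpy()
        g = sig["elevation"].to_numpy()
        l = sig["inclination"].to_numpy()
        expect = sum(ai * gi for ai, gi, li in zip(a, g, l) if li > 135) / \
            sum(ai * gi for ai, gi, li in zip(a, g, l) if li < 135)
        assert np.isclose(gam, expect)


class TestClassicReliefIndex:
    def test_flat_disc_is_one(self):
        m, _ = make_primitive("plane", resolution=3, size=2.0, z=1.0)
        assert abs(classic_relief_index(m, np.ones(m.n_faces, bool)) - 1.0) \
            < 1e-9

    def test_hemisphere_is_two(self):
        m, _ = make_primitive("hemisphere", resolution=5, radius=1.0)
        ri = classic_relief_index(m, np.ones(m.n_faces, bool))
        assert abs(ri - 2.0) < 0.02

    def test_union_matches_rasterization_oracle(self, small_tooth):
        """Projected area must count overlaps once; cross-check against a
        fine-grid rasterization of the projected triangles."""
        oes, edj, lm, _ = small_tooth
        from dentopo import align_to_landmarks
        _, e2, _ = align_to_landmarks(oes, edj, lm)
        roi = occlusal_roi(e2, z_cut=float(e2.vertices[:, 2].max()) - 2.5)
        ri = classic_relief_index(e2, roi)

        tri = e2.triangles[roi][:, :, :2]
        lo = tri.reshape(-1, 2).min(0) - 0.05
        hi = tri.reshape(-1, 2).max(0) + 0.05
        n = 700
        xs = np.linspace(lo[0], hi[0], n)
        ys = np.linspace(lo[1], hi[1], n)
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        def cross2(u, v):
            return u[0] * v[:, 1] - u[1] * v[:, 0]

        covered = np.zeros(len(pts), dtype=bool)
        for t in tri:
            d1 = cross2(t[1] - t[0], pts - t[0])
            d2 = cross2(t[2] - t[1], pts - t[1])
            d3 = cross2(t[0] - t[2], pts - t[2])
            covered |= ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | \
                       ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        a2d_ref = covered.sum() * cell
        a3d = e2.face_areas()[roi].sum()
        assert abs(ri / (a3d / a2d_ref) - 1.0) < 0.02


class TestProfiles:
    def test_single_bin(self):
        p = binned_area_profile(np.full(5, 150.0), np.ones(5), (0, 180), 15.0)
        assert np.isclose(p.fraction[10], 1.0)  # [150, 165)
        assert np.isclose(p.fraction.sum(), 1.0)

    def test_cone_orientation_uniform(self):
        """Azimuthally symmetric cone: each of the eight 45-degree bins
        holds exactly 12.5 % of the area."""
        m, _ = make_primitive("cone", resolution=4, half_angle_deg=45.0)
        sig = compute_signifiers(m, with_curvature=False)
        p = binned_area_profile(sig["orientation"], sig["area"], (0, 360),
                                45.0)
        assert np.allclose(p.fraction, 0.125, atol=1e-9)

    def test_fractions_sum_to_one(self, small_tooth):
        _, edj, _, _ = small_tooth
        sig = compute_signifiers(edj, with_curvature=False)
        p = binned_area_profile(sig["inclination"], sig["area"], (0, 180),
                                15.0)
        assert np.isclose(p.fraction.sum(), 1.0, atol=1e-9)
        assert len(p.area) == 12

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            binned_area_profile(np.ones(3), np.ones(3), (0, 180), 14.0)


class TestCurvatureIndices:
    def test_arithmetic(self):
        phi_p, phi_mci = curvature_indices(
            area=np.array([1.0, 1.0, 2.0]),
            phi_std=np.array([0.5, 0.3, -0.2]), crest_threshold=0.4)
        assert np.isclose(phi_mci, (0.5 + 0.3) / 4.0)
        assert np.isclose(phi_p, 0.25)

    def test_flat_surface_zero(self):
        phi_p, phi_mci = curvature_indices(np.ones(4), np.zeros(4), 0.1)
        assert phi_p == 0.0 and phi_mci == 0.0

    def test_sharpening_increases_convexity_index(self):
        """Narrower cusps at fixed height -> strictly larger phi_mci."""
        vals = []
        for sharp in (1.0, 0.85, 0.7):
            _, edj, lm, _ = make_synthetic_tooth(
                SyntheticToothSpec(target_faces=6000, seed=21,
                                   thickness=0.0, cusp_sharpness=sharp))
            phi, bnd = mean_curvature(edj)
            area = edj.face_areas()
            _, phi_mci = curvature_indices(area[~bnd], phi[~bnd], np.inf)
            vals.append(phi_mci)
        assert vals[0] < vals[1] < vals[2]


def test_blunting_index():
    assert np.isclose(blunting_index(0.5, 0.4), 1.25)
    with pytest.raises(ValueError):
        blunting_index(0.5, 0.0)


def test_relative_complexity():
    assert np.isclose(relative_complexity(80, 60), 80 / 60)
    assert relative_complexity(7, 7) == 1.0
    with pytest.raises(ValueError):
        relative_complexity(5, 0)


def test_relief_indices_vary_conversely():
    """Across a graded-relief crown family the flat-to-steep index and the
    classic relief index move in opposite directions."""
    from dentopo import align_to_landmarks
    gammas, ris = [], []
    for relief in (0.6, 0.85, 1.1, 1.35):
        oes, edj, lm, _ = make_synthetic_tooth(
            SyntheticToothSpec(target_faces=6000, seed=31, relief=relief,
                               thickness=0.4))
        _, e2, tf = align_to_landmarks(oes, edj, lm)
        sig = compute_signifiers(e2, with_curvature=False)
        roi = occlusal_roi(e2, tips=tf.apply(lm.tips))
        gammas.append(relief_index(sig["area"][roi], sig["elevation"][roi],
                                   sig["inclination"][roi]))
        ris.append(classic_relief_index(e2, roi))
    assert all(a > b for a, b in zip(gammas, gammas[1:]))   # Gamma falls
    assert all(a < b for a, b in zip(ris, ris[1:]))         # RI rises
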