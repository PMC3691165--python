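"""Per-polygon signifiers: geometry, orientation, inclination, curvature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentopo import (TriangleMesh, compute_signifiers, enclosed_volume,
                     face_geometry, inclination, mean_curvature, orientation,
                     standardize_curvature)
from dentopo.synthetic import make_primitive

from conftest import random_rigid


def test_face_geometry_closed_form():
    # right triangle, legs 1 and 1, lying in z = 2
    m = TriangleMesh(np.array([[0, 0, 2], [1, 0, 2], [0, 1, 2.0]]),
                     np.array([[0, 1, 2]]))
    df = face_geometry(m)
    assert np.isclose(df["area"][0], 0.5)
    assert np.isclose(df["elevation"][0], 2.0)
    assert np.allclose(df[["nx", "ny", "nz"]].iloc[0], [0, 0, 1])


def test_elevation_equivariant_under_z_shift(small_tooth):
    _, edj, _, _ = small_tooth
    df0 = face_geometry(edj)
    shifted = edj.copy()
    shifted.vertices = shifted.vertices + [0, 0, 3.0]
    df1 = face_geometry(shifted)
    assert np.allclose(df1["elevation"] - df0["elevation"], 3.0)


def test_sphere_area_sums_to_4pi():
    m, _ = make_primitive("sphere", resolution=4, radius=1.0)
    assert abs(face_geometry(m)["area"].sum() / (4 * np.pi) - 1) < 0.01


@pytest.mark.parametrize("n,psi", [
    ((0.0, 1.0, 0.0), 90.0),
    ((-np.sqrt(2) / 2, -np.sqrt(2) / 2, 0.0), 225.0),
    ((1.0, 0.0, 0.0), 0.0),
    ((0.0, -1.0, 0.0), 270.0),
])
def test_orientation_axis_cases(n, psi):
    assert np.isclose(orientation(np.array(n)), psi)


def test_orientation_undefined_for_horizontal():
    assert np.isnan(orientation(np.array([0.0, 0.0, 1.0])))
    assert np.isnan(orientation(np.array([0.0, 0.0, -1.0])))


@pytest.mark.parametrize("n,lam", [
    ((0.0, 0.0, 1.0), 180.0),   # horizontal up-facing facet
    ((1.0, 0.0, 0.0), 90.0),    # vertical wall
    ((0.0, 0.0, -1.0), 0.0),    # fully re-entrant limit
    ((np.sqrt(2) / 2, 0.0, np.sqrt(2) / 2), 135.0),
])
def test_inclination_coding(n, lam):
    assert np.isclose(inclination(np.array(n)), lam)


@given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1))
@settings(max_examples=200, deadline=None)
def test_inclination_antipodal_sum(nx, ny, nz):
    """lambda(n) + lambda(-n) = 180 for every direction."""
    v = np.array([nx, ny, nz])
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        return
    v = v / norm
    assert np.isclose(inclination(v) + inclination(-v), 180.0, atol=1e-9)


def test_orientation_equivariant_under_z_rotation(small_tooth):
    _, edj, _, _ = small_tooth
    sig0 = compute_signifiers(edj, with_curvature=False)
    theta = 73.0
    c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    rot = edj.copy()
    rot.vertices = rot.vertices @ R.T
    sig1 = compute_signifiers(rot, with_curvature=False)
    both = sig0["orientation_defined"] & sig1["orientation_defined"]
    d = (sig1.loc[both, "orientation"] - sig0.loc[both, "orientation"]
         - theta) % 360.0
    d = np.minimum(d, 360 - d)
    assert d.max() < 1e-6


class TestMeanCurvature:
    def test_sphere(self):
        m, _ = make_primitive("sphere", resolution=4, radius=1.0)
        phi, _ = mean_curvature(m)
        assert np.abs(phi - 1.0).max() < 0.02

    def test_plane_interior_flat(self):
        m, _ = make_primitive("plane", resolution=4, size=2.0)
        phi, bnd = mean_curvature(m)
        assert np.abs(phi[~bnd]).max() < 1e-3

    def test_cylinder_interior(self):
        m, _ = make_primitive("cylinder", resolution=4, radius=2.0,
                              height=4.0)
        phi, bnd = mean_curvature(m)
        assert np.abs(phi[~bnd] / 0.25 - 1.0).max() < 0.03

    def test_concave_sign(self):
        """A bowl (inward-facing hemisphere seen from above) is concave:
        negative curvature toward the outward (up) normal."""
        m, _ = make_primitive("hemisphere", resolution=3, radius=2.0)
        bowl = m.copy()
        # mirroring z flips winding too, so the normal field already points
        # up into the cavity; no face reversal needed
        bowl.vertices = bowl.vertices * [1.0, 1.0, -1.0]
        bowl.vertices[:, 2] += 2.0
        phi, bnd = mean_curvature(bowl)
        assert phi[~bnd].mean() < -0.4

    def test_rigid_invariance(self, small_tooth):
        _, edj, _, _ = small_tooth
        phi0, bnd = mean_curvature(edj)
        R, t = random_rigid(5)
        m = edj.copy()
        m.vertices = m.vertices @ R.T + t
        phi1, _ = mean_curvature(m)
        scale = np.abs(phi0[~bnd]).max()
        assert np.abs(phi1[~bnd] - phi0[~bnd]).max() < 1e-3 * scale


class TestStandardizedCurvature:
    def test_self_reference_is_identity(self, small_tooth):
        _, edj, _, _ = small_tooth
        phi, _ = mean_curvature(edj)
        assert np.array_equal(standardize_curvature(phi, edj, None), phi)

    def test_arithmetic(self, small_tooth):
        _, edj, _, _ = small_tooth
        v = enclosed_volume(edj)
        out = standardize_curvature(np.array([0.5]), edj,
                                    reference_volume=v / 8.0)
        assert np.isclose(out[0], 1.0)

    def test_scale_invariance(self, small_tooth):
        """phi ~ 1/k and V^(1/3) ~ k cancel: standardized curvature of a
        scaled crown equals the original's under a fixed reference."""
        _, edj, _, _ = small_tooth
        phi0, bnd = mean_curvature(edj)
        ref = enclosed_volume(edj)
        big = edj.copy()
        big.vertices = big.vertices * 2.0
        phi1, _ = mean_curvature(big)
        s0 = standardize_curvature(phi0, edj, ref)
        s1 = standardize_curvature(phi1, big, ref)
        keep = ~bnd & (np.abs(s0) > 1e-3)
        assert np.abs(s1[keep] / s0[keep] - 1.0).max() < 1e-4

    def test_volume_hemisphere(self):
        m, _ = make_primitive("hemisphere", resolution=5, radius=3.0)
        expect = 2.0 / 3.0 * np.pi * 27.0
        assert abs(enclosed_volume(m) / expect - 1.0) < 0.01


def test_signifier_table_consistency(small_tooth):
    _, edj, _, _ = small_tooth
    sig = compute_signifiers(edj)
    assert len(sig) == edj.n_faces
    assert np.isclose(sig["area"].sum(), edj.total_area())
    norms = np.linalg.norm(sig[["nx", "ny", "nz"]], axis=1)
    assert np.abs(norms - 1.0).max() < 1e-9
    assert sig["inclination"].between(0, 180).all()
    defined = sig["orientation_defined"]
    assert sig.loc[defined, "orientation"].between(0, 360, "left").all()
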