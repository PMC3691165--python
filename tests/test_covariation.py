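"""Paired OES/EDJ signifiers and resampled correlations."""

import numpy as np
import pandas as pd
import pytest

from dentopo import (build_paired_table, compute_signifiers,
                     correlation_matrix, resampled_correlation,
                     thickness_field)
from dentopo.synthetic import make_primitive


def test_identity_pair_has_zero_delta_and_equal_signifiers(small_tooth):
    """OES identical to EDJ: every row pairs a face with itself-like values
    and delta = 0."""
    _, edj, _, _ = small_tooth
    sig = compute_signifiers(edj, with_curvature=False)
    tf = thickness_field(edj, edj)
    pt = build_paired_table(tf, sig, sig)
    assert len(pt) == edj.n_faces
    assert np.abs(pt["delta"]).max() < 1e-12
    assert np.allclose(pt["lambda_oes"], pt["lambda_edj"], atol=1e-9)
    assert np.allclose(pt["gamma_oes"], pt["gamma_edj"], atol=1e-9)


def test_parallel_shells_pair_rowwise(small_tooth):
    oes, edj, _ = make_primitive("concentric_shells", resolution=3,
                                 r_inner=5.0, r_outer=6.0)
    sig_o = compute_signifiers(oes, with_curvature=False)
    sig_e = compute_signifiers(edj, with_curvature=False)
    tf = thickness_field(oes, edj)
    pt = build_paired_table(tf, sig_o, sig_e)
    d = np.abs(pt["lambda_oes"] - pt["lambda_edj"])
    assert np.quantile(d, 0.95) < 3.0  # parallel surfaces, same inclination


def test_roi_restricts_rows(small_tooth):
    oes, edj, _, _ = small_tooth
    sig_o = compute_signifiers(oes, with_curvature=False)
    sig_e = compute_signifiers(edj, with_curvature=False)
    tf = thickness_field(oes, edj)
    roi = np.zeros(oes.n_faces, dtype=bool)
    roi[: oes.n_faces // 3] = True
    pt = build_paired_table(tf, sig_o, sig_e, roi)
    assert len(pt) == roi.sum()


def _table(x, y):
    return pd.DataFrame({"a": x, "b": y})


class TestResampledCorrelation:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 2000)
        res = resampled_correlation(_table(x, x), [("a", "b")],
                                    n_subsamples=20, subsample_size=500,
                                    seed=1)[0]
        assert np.allclose(res.r_values, 1.0)
        assert res.fraction_significant == 1.0

    def test_null_type_one_error(self):
        """Independent normals: the fraction of significant subsamples
        matches the null rate.  Subsamples are drawn from one finite base
        sample, so the proper expectation conditions on that sample's
        empirical r (itself ~ N(0, 1/sqrt(n)))."""
        from scipy import stats
        rng = np.random.default_rng(12345)
        n, m = 5000, 1000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = resampled_correlation(_table(x, y), [("a", "b")],
                                    n_subsamples=130, subsample_size=m,
                                    alpha=0.01, seed=2)[0]
        r_emp = np.corrcoef(x, y)[0, 1]
        t_crit = stats.t.ppf(1 - 0.005, df=m - 2)
        r_crit = t_crit / np.sqrt(m - 2 + t_crit ** 2)
        p_hit = (stats.norm.sf((r_crit - r_emp) * np.sqrt(m))
                 + stats.norm.cdf((-r_crit - r_emp) * np.sqrt(m)))
        sigma = np.sqrt(p_hit * (1 - p_hit) / 130)
        assert abs(res.fraction_significant - p_hit) <= 3 * sigma + 1 / 130

    def test_recovers_rho_half(self):
        rng = np.random.default_rng(99)
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        res = resampled_correlation(_table(x, y), [("a", "b")],
                                    n_subsamples=130, subsample_size=1000,
                                    seed=3)[0]
        se = (1 - 0.25) / np.sqrt(1000)
        assert abs(res.mean_r - 0.5) < 3 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        a = resampled_correlation(_table(x, y), [("a", "b")],
                                  n_subsamples=10, seed=42)[0]
        b = resampled_correlation(_table(x, y), [("a", "b")],
                                  n_subsamples=10, seed=42)[0]
        assert np.array_equal(a.r_values, b.r_values)
        c = resampled_correlation(_table(x, y), [("a", "b")],
                                  n_subsamples=10, seed=43)[0]
        assert not np.array_equal(a.r_values, c.r_values)

    def test_constant_column_flagged(self):
        res = resampled_correlation(_table(np.ones(100),
                                           np.arange(100.0)),
                                    [("a", "b")], n_subsamples=5,
                                    subsample_size=50, seed=1)[0]
        assert np.isnan(res.r_values).all()
        assert any("constant" in n for n in res.notes)

    def test_small_table_warns(self):
        with pytest.warns(UserWarning, match="subsample"):
            resampled_correlation(_table(np.arange(10.0),
                                         np.arange(10.0)),
                                  [("a", "b")], n_subsamples=3,
                                  subsample_size=1000, seed=1)

    def test_circularity_note_for_orientation(self):
        pt = pd.DataFrame({"psi_oes": np.arange(100.0) % 360,
                           "delta": np.arange(100.0)})
        res = resampled_correlation(pt, [("psi_oes", "delta")],
                                    n_subsamples=3, subsample_size=50,
                                    seed=1)[0]
        assert any("circular" in n for n in res.notes)


def test_correlation_matrix_symmetric_unit_diagonal(small_tooth):
    oes, edj, _, _ = small_tooth
    sig_o = compute_signifiers(oes)
    sig_e = compute_signifiers(edj)
    tf = thickness_field(oes, edj)
    pt = build_paired_table(tf, sig_o, sig_e)
    cm = correlation_matrix(pt)
    assert np.allclose(cm.values, cm.values.T, equal_nan=True)
    assert np.allclose(np.diag(cm.values), 1.0)
    assert cm.shape == (9, 9)
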