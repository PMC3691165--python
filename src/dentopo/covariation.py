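"""Pairing OES and EDJ signifiers through the thickness correspondence and
estimating their correlation with resampling.

Each OES occlusal face contributes one row: its enamel thickness delta and
its four signifiers, joined with the signifiers of its matched EDJ face.
Correlations between selected variable pairs are evaluated on repeated
subsamples drawn with replacement (default: 130 subsamples of 1000 rows),
reporting the per-subsample Pearson r and the fraction significant at the
chosen alpha (two-sided t test).

Orientation (psi) is a circular variable; following common practice for
these profiles it is correlated linearly, and a circularity caveat is
attached to any result involving psi.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .thickness import ThicknessField

log = logging.getLogger("dentopo")

__all__ = ["PairedSignifiers", "CorrelationResult", "build_paired_table",
           "resampled_correlation", "correlation_matrix"]

PAIR_COLUMNS = ["delta",
                "gamma_oes", "lambda_oes", "psi_oes", "phi_oes",
                "gamma_edj", "lambda_edj", "psi_edj", "phi_edj"]


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    n_subsamples: int
    subsample_size: int
    r_values: np.ndarray
    significant: np.ndarray
    alpha: float
    seed: int
    method: str = "pearson"
    notes: list = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        ok = np.isfinite(self.r_values)
        return float(np.mean(self.r_values[ok])) if ok.any() else float("nan")

    @property
    def fraction_significant(self) -> float:
        ok = np.isfinite(self.r_values)
        return float(np.mean(self.significant[ok])) if ok.any() else float("nan")

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "n_subsamples": self.n_subsamples,
            "subsample_size": self.subsample_size,
            "mean_r": self.mean_r,
            "fraction_significant": self.fraction_significant,
            "alpha": self.alpha,
            "seed": self.seed,
            "method": self.method,
            "notes": self.notes,
            "r_values": [float(r) for r in self.r_values],
        }


def build_paired_table(tf: ThicknessField, sig_oes: pd.DataFrame,
                       sig_edj: pd.DataFrame,
                       oes_roi: np.ndarray | None = None) -> pd.DataFrame:
    """One row per OES (ROI) face: delta plus the four signifiers of the OES
    face and of its matched EDJ face."""
    n = len(sig_oes)
    if len(tf.face_delta) != n:
        raise ValueError("thickness field and OES signifier table refer to "
                         "different face sets")
    if tf.face_match.max() >= len(sig_edj):
        raise ValueError("correspondence refers to EDJ faces missing from "
                         "the EDJ signifier table")
    rows = np.arange(n) if oes_roi is None else np.where(oes_roi)[0]
    match = tf.face_match[rows]
    phi_oes = (sig_oes["mean_curvature"].to_numpy()
               if "mean_curvature" in sig_oes else np.full(n, np.nan))
    phi_edj = (sig_edj["mean_curvature"].to_numpy()
               if "mean_curvature" in sig_edj else np.full(len(sig_edj), np.nan))
    return pd.DataFrame({
        "oes_face_id": rows,
        "edj_face_id": match,
        "delta": tf.face_delta[rows],
        "gamma_oes": sig_oes["elevation"].to_numpy()[rows],
        "lambda_oes": sig_oes["inclination"].to_numpy()[rows],
        "psi_oes": sig_oes["orientation"].to_numpy()[rows],
        "phi_oes": phi_oes[rows],
        "gamma_edj": sig_edj["elevation"].to_numpy()[match],
        "lambda_edj": sig_edj["inclination"].to_numpy()[match],
        "psi_edj": sig_edj["orientation"].to_numpy()[match],
        "phi_edj": phi_edj[match],
    })


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def resampled_correlation(pt: pd.DataFrame, pairs: list[tuple[str, str]],
                          n_subsamples: int = 130, subsample_size: int = 1000,
                          alpha: float = 0.01, seed: int = 0,
                          method: str = "pearson") -> list[CorrelationResult]:
    """Per variable pair: Pearson (or Spearman) r on ``n_subsamples``
    subsamples of ``subsample_size`` rows drawn with replacement, with
    two-sided significance at ``alpha``.  Deterministic under a fixed seed.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    results = []
    for ci, (ax, ay) in enumerate(pairs):
        if ax not in pt.columns or ay not in pt.columns:
            raise KeyError(f"unknown variable pair ({ax}, {ay})")
        sub = pt[[ax, ay]].dropna()
        x = sub[ax].to_numpy(dtype=np.float64)
        y = sub[ay].to_numpy(dtype=np.float64)
        n = len(x)
        notes = []
        if n < subsample_size:
            warnings.warn(f"table has {n} rows < subsample size "
                          f"{subsample_size}; resampling with replacement "
                          "proceeds")
            notes.append("table smaller than subsample size")
        if "psi" in ax or "psi" in ay:
            notes.append("orientation is circular; linear correlation "
                         "reported for comparability")
        rng = np.random.default_rng([seed, ci])
        rs = np.empty(n_subsamples)
        sig = np.zeros(n_subsamples, dtype=bool)
        crit = stats.t.ppf(1 - alpha / 2, df=subsample_size - 2)
        for i in range(n_subsamples):
            idx = rng.integers(0, n, size=subsample_size)
            xi, yi = x[idx], y[idx]
            if method == "spearman":
                xi = stats.rankdata(xi)
                yi = stats.rankdata(yi)
            r = _pearson(xi, yi)
            rs[i] = r
            if np.isfinite(r) and abs(r) < 1:
                t = abs(r) * np.sqrt((subsample_size - 2) / (1 - r * r))
                sig[i] = t > crit
            elif np.isfinite(r):
                sig[i] = True
        if not np.isfinite(rs).all():
            notes.append(f"{int((~np.isfinite(rs)).sum())} subsample(s) with "
                         "a constant column; r undefined there")
        results.append(CorrelationResult(
            pair=(ax, ay), n_subsamples=n_subsamples,
            subsample_size=subsample_size, r_values=rs, significant=sig,
            alpha=alpha, seed=seed, method=method, notes=notes))
    return results


def correlation_matrix(pt: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Full correlation matrix of the paired variables (pairwise-complete
    Pearson r; symmetric with unit diagonal)."""
    cols = columns or [c for c in PAIR_COLUMNS if c in pt.columns]
    return pt[cols].corr(method="pearson")
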