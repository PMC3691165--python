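"""Full analysis pipeline: from an aligned (or alignable) OES/EDJ pair and
its landmarks to signifier tables, thickness field, patch sets, indices,
profiles, correlations and exported morphometric maps.

All outputs are deterministic given the configuration and seed; every file
carries the config hash and package version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (LandmarkSet, RigidTransform, align_to_landmarks,
                        occlusal_roi, read_landmarks)
from .complexity import bin_orientation, complexity_summary, find_patches
from .config import AnalysisConfig
from .covariation import (build_paired_table, correlation_matrix,
                          resampled_correlation)
from .indices import (IndexReport, binned_area_profile, blunting_index,
                      classic_relief_index, crest_threshold_rule,
                      curvature_indices, relative_complexity, relief_index,
                      thickness_stats)
from .mesh import TriangleMesh, read_mesh, retessellate, validate_mesh, write_mesh
from .signifiers import compute_signifiers, enclosed_volume
from .thickness import thickness_field

log = logging.getLogger("dentopo")

__all__ = ["AnalysisResult", "run_analysis", "analyze_pair", "export_maps"]

MAP_SIGNIFIERS = ("thickness", "elevation", "inclination", "orientation",
                  "curvature")


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    transform: RigidTransform
    oes: TriangleMesh
    edj: TriangleMesh
    sig_oes: pd.DataFrame
    sig_edj: pd.DataFrame
    roi_oes: np.ndarray
    roi_edj: np.ndarray
    thickness: "object"
    patches_oes: "object"
    patches_edj: "object"
    report_oes: IndexReport
    report_edj: IndexReport
    report_pair: IndexReport
    profiles: list
    paired: pd.DataFrame
    correlations: list
    corr_matrix: pd.DataFrame
    crest_threshold: float
    timings: dict = field(default_factory=dict)


def _stage(timings, name):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc_type is not None:
                log.error("stage %s failed: %s", name, exc)
            else:
                log.debug("stage %s done in %.2fs", name, timings[name])
            return False
    return _T()


def analyze_pair(oes: TriangleMesh, edj: TriangleMesh, lm: LandmarkSet,
                 config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the complete analysis on in-memory meshes."""
    cfg = (config or AnalysisConfig()).validate()
    timings: dict = {}

    with _stage(timings, "validate"):
        for name, m in (("OES", oes), ("EDJ", edj)):
            rep = validate_mesh(m)
            if rep.n_degenerate_faces:
                log.warning("%s: %d degenerate faces", name,
                            rep.n_degenerate_faces)

    if cfg.retessellate:
        with _stage(timings, "retessellate"):
            oes = retessellate(oes, cfg.target_face_count)
            edj = retessellate(edj, cfg.target_face_count)

    with _stage(timings, "align"):
        oes, edj, tf = align_to_landmarks(oes, edj, lm)

    with _stage(timings, "signifiers"):
        ref_vol = cfg.reference_volume
        sig_oes = compute_signifiers(oes, reference_volume=ref_vol)
        sig_edj = compute_signifiers(edj, reference_volume=ref_vol)

    with _stage(timings, "roi"):
        if cfg.roi_mode == "none":
            roi_oes = np.ones(oes.n_faces, dtype=bool)
            roi_edj = np.ones(edj.n_faces, dtype=bool)
        elif cfg.roi_mode == "z_cut":
            roi_oes = occlusal_roi(oes, z_cut=cfg.roi_z_cut)
            roi_edj = occlusal_roi(edj, z_cut=cfg.roi_z_cut)
        elif cfg.roi_mode == "landmarks":
            if lm.basin_point_oes is None or lm.basin_point_edj is None:
                raise ValueError("roi_mode 'landmarks' needs basin points")
            roi_oes = occlusal_roi(oes, basin_point=tf.apply(
                lm.basin_point_oes) + [0, 0, tf.z_offsets["oes"]
                                       - tf.z_offsets["edj"]])
            roi_edj = occlusal_roi(edj, basin_point=tf.apply(
                lm.basin_point_edj))
        else:  # auto: lowest vertex inside the tip triangle, per surface
            tips = tf.apply(lm.tips)
            roi_oes = occlusal_roi(oes, tips=tips)
            roi_edj = occlusal_roi(edj, tips=tips)

    with _stage(timings, "thickness"):
        # thickness is a property of the pair's common frame: undo the
        # per-mesh cervix z-zeroing (which serves elevation only) before
        # measuring OES -> EDJ distances
        oes_common = oes.copy()
        oes_common.vertices = oes_common.vertices.copy()
        oes_common.vertices[:, 2] -= (tf.z_offsets["oes"]
                                      - tf.z_offsets["edj"])
        tfield = thickness_field(oes_common, edj)

    with _stage(timings, "complexity"):
        patch = {}
        for tag, mesh_, sig, roi in (("oes", oes, sig_oes, roi_oes),
                                     ("edj", edj, sig_edj, roi_edj)):
            psi = sig["orientation"].to_numpy().copy()
            psi[~roi] = np.nan  # occlusal ROI only
            labels = bin_orientation(psi, cfg.orientation_bin_width)
            patch[tag] = find_patches(mesh_, labels, cfg.min_patch_size,
                                      cfg.orientation_bin_width)

    with _stage(timings, "indices"):
        crest_ref = sig_edj.loc[roi_edj, "phi_std"].to_numpy()
        crest_thr = crest_threshold_rule(crest_ref, cfg.crest_quantile)

        area_oes = sig_oes["area"].to_numpy()
        area_edj = sig_edj["area"].to_numpy()
        a_edj_roi = float(area_edj[roi_edj].sum())
        d_mean, d_sd, d_st = thickness_stats(
            tfield.face_delta[roi_oes], area_oes[roi_oes], a_edj_roi)

        reports = {}
        for tag, sig, mesh_, roi, ps in (
                ("oes", sig_oes, oes, roi_oes, patch["oes"]),
                ("edj", sig_edj, edj, roi_edj, patch["edj"])):
            gam = relief_index(sig["area"][roi], sig["elevation"][roi],
                               sig["inclination"][roi], cfg.relief_threshold)
            ric = classic_relief_index(mesh_, roi)
            phi_p, phi_mci = curvature_indices(sig["area"][roi],
                                               sig["phi_std"][roi], crest_thr)
            reports[tag] = IndexReport(
                surface=tag.upper(), gamma=gam, ri_classic=ric,
                psi_c=ps.total_count, phi_p=phi_p, phi_mci=phi_mci)
        reports["oes"].delta_mean = d_mean
        reports["oes"].delta_sd = d_sd
        reports["oes"].delta_st = d_st

        dentine_vol = enclosed_volume(edj)
        pair = IndexReport(
            surface="PAIR",
            delta_mean=d_mean, delta_sd=d_sd, delta_st=d_st,
            phi_bi=blunting_index(reports["edj"].phi_p, reports["oes"].phi_p)
            if reports["oes"].phi_p > 0 else None,
            psi_c_ratio=relative_complexity(reports["oes"].psi_c,
                                            reports["edj"].psi_c)
            if reports["edj"].psi_c > 0 else None,
            relief_accentuation=reports["oes"].gamma / reports["edj"].gamma,
            scale_free_thickness=d_mean / dentine_vol ** (1 / 3),
        )

        profiles = []
        for tag, sig, roi in (("oes", sig_oes, roi_oes),
                              ("edj", sig_edj, roi_edj)):
            profiles.append(binned_area_profile(
                sig["inclination"][roi], sig["area"][roi], (0, 180),
                cfg.inclination_bin_width, f"lambda_v_{tag}"))
            profiles.append(binned_area_profile(
                sig["orientation"][roi], sig["area"][roi], (0, 360),
                cfg.orientation_bin_width, f"psi_v_{tag}"))
            profiles.append(binned_area_profile(
                sig["phi_std"][roi], sig["area"][roi],
                _phi_range(sig["phi_std"][roi]), _phi_width(sig["phi_std"][roi]),
                f"phi_v_{tag}"))
        profiles.append(binned_area_profile(
            tfield.face_delta[roi_oes], area_oes[roi_oes],
            _delta_range(tfield.face_delta[roi_oes]), 0.1, "delta_dist"))

    with _stage(timings, "covariation"):
        paired = build_paired_table(tfield, sig_oes, sig_edj, roi_oes)
        pairs = [tuple(p) for p in cfg.correlation_pairs]
        corrs = resampled_correlation(
            paired, pairs, n_subsamples=cfg.n_subsamples,
            subsample_size=cfg.subsample_size, alpha=cfg.alpha,
            seed=cfg.seed, method=cfg.correlation_method)
        cmat = correlation_matrix(paired)

    return AnalysisResult(
        config=cfg, transform=tf, oes=oes, edj=edj,
        sig_oes=sig_oes, sig_edj=sig_edj, roi_oes=roi_oes, roi_edj=roi_edj,
        thickness=tfield, patches_oes=patch["oes"], patches_edj=patch["edj"],
        report_oes=reports["oes"], report_edj=reports["edj"],
        report_pair=pair, profiles=profiles, paired=paired,
        correlations=corrs, corr_matrix=cmat, crest_threshold=crest_thr,
        timings=timings)


def _phi_width(phi):
    return 0.25


def _phi_range(phi):
    v = np.asarray(phi)
    v = v[np.isfinite(v)]
    w = _phi_width(v)
    lo = np.floor(v.min() / w) * w if len(v) else 0.0
    hi = np.ceil(v.max() / w) * w if len(v) else w
    if hi <= lo:
        hi = lo + w
    return float(lo), float(hi)


def _delta_range(d):
    hi = np.ceil(max(float(np.max(d)), 0.1) / 0.1) * 0.1
    return 0.0, float(hi)


def run_analysis(oes_path, edj_path, landmarks_path,
                 config: AnalysisConfig | None = None,
                 outdir="dentopo_out") -> AnalysisResult:
    """File-level pipeline entry point: read, analyze, write everything."""
    cfg = (config or AnalysisConfig()).validate()
    lm = read_landmarks(landmarks_path)  # fail before heavy I/O if missing
    oes = read_mesh(oes_path)
    edj = read_mesh(edj_path)
    res = analyze_pair(oes, edj, lm, cfg)
    write_outputs(res, outdir)
    return res


def write_outputs(res: AnalysisResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": res.config.hash(), "version": __version__}

    res.transform.to_json(out / "transform.json")
    res.config.to_yaml(out / "config.yaml")

    for tag, sig, roi, ps in (("oes", res.sig_oes, res.roi_oes, res.patches_oes),
                              ("edj", res.sig_edj, res.roi_edj, res.patches_edj)):
        df = sig.copy()
        df["roi"] = roi
        df["patch_id"] = ps.face_patch_id
        _to_csv(df, out / f"signifiers_{tag}.csv", meta)
        _to_csv(complexity_summary(ps), out / f"complexity_{tag}.csv", meta)
        _to_csv(ps.patches, out / f"patches_{tag}.csv", meta)

    _to_csv(res.thickness.correspondence_table(),
            out / "correspondence.csv", meta)
    _to_csv(pd.concat([p.to_frame() for p in res.profiles]),
            out / "profiles.csv", meta)
    _to_csv(res.paired, out / "paired_signifiers.csv", meta)
    _to_csv(res.corr_matrix.reset_index(names="variable"),
            out / "correlation_matrix.csv", meta)

    indices = {
        "meta": {**meta, "crest_threshold": res.crest_threshold,
                 "orientation_zero": "+x, counter-clockwise from +z",
                 "target_face_count": res.config.target_face_count,
                 "min_patch_size": res.config.min_patch_size},
        "oes": res.report_oes.to_dict(),
        "edj": res.report_edj.to_dict(),
        "pair": res.report_pair.to_dict(),
    }
    (out / "indices.json").write_text(json.dumps(indices, indent=2,
                                                 default=_json_default))
    rows = [res.report_oes.to_dict(), res.report_edj.to_dict(),
            res.report_pair.to_dict()]
    _to_csv(pd.DataFrame(rows), out / "indices.csv", meta)

    (out / "correlations.json").write_text(json.dumps(
        {"meta": meta, "results": [c.to_dict() for c in res.correlations]},
        indent=2, default=_json_default))
    corr_rows = []
    for c in res.correlations:
        for i, r in enumerate(c.r_values):
            corr_rows.append({"pair": "/".join(c.pair), "subsample": i,
                              "r": r, "significant": bool(c.significant[i])})
    _to_csv(pd.DataFrame(corr_rows), out / "correlations.csv", meta)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _to_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# dentopo {meta['version']} config={meta['config_hash']}\n")
        df.to_csv(fh, index=False)


def export_maps(res: AnalysisResult, outdir, which=None,
                scale_bounds: dict | None = None) -> list:
    """Write one colored PLY per signifier per surface (morphometric maps);
    color-scale bounds are recorded in a sidecar JSON."""
    which = list(which or MAP_SIGNIFIERS)
    unknown = set(which) - set(MAP_SIGNIFIERS)
    if unknown:
        raise ValueError(f"unknown signifier name(s): {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scale_bounds = scale_bounds or {}
    written = []
    sidecar = {}
    for tag, mesh_, sig in (("oes", res.oes, res.sig_oes),
                            ("edj", res.edj, res.sig_edj)):
        values = {
            "thickness": (res.thickness.face_delta if tag == "oes" else None),
            "elevation": sig["elevation"].to_numpy(),
            "inclination": sig["inclination"].to_numpy(),
            "orientation": sig["orientation"].to_numpy(),
            "curvature": sig["phi_std"].to_numpy(),
        }
        for name in which:
            v = values[name]
            if v is None:
                continue
            m = mesh_.copy()
            m.per_face_attrs[name] = np.asarray(v, dtype=np.float64)
            bounds = scale_bounds.get(name)
            if bounds is None:
                finite = np.asarray(v)[np.isfinite(v)]
                bounds = (float(finite.min()), float(finite.max())) \
                    if len(finite) else (0.0, 1.0)
            path = out / f"map_{tag}_{name}.ply"
            write_mesh(m, path, scalars=name,
                       colormap="viridis", scale_bounds=bounds)
            sidecar[f"{tag}/{name}"] = {"bounds": list(bounds),
                                        "colormap": "viridis"}
            written.append(path)
    (out / "maps_scales.json").write_text(json.dumps(sidecar, indent=2))
    return written
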