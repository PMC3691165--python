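"""Analysis configuration: every numeric choice of the pipeline in one
validated, hashable, YAML-round-trippable record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    orientation_bin_width: float = 45.0   # deg; 360 / width bins
    inclination_bin_width: float = 15.0   # deg; 180 / width bins
    relief_threshold: float = 135.0       # deg, flat/steep split for Gamma
    min_patch_size: int = 3               # faces, retained inclusively
    crest_quantile: float = 0.9           # crest threshold rule (see docs)
    target_face_count: int = 22000
    reference_volume: float | None = None  # mm^3; None -> each mesh is its own
    retessellate: bool = True
    roi_mode: str = "auto"                # auto | landmarks | z_cut | none
    roi_z_cut: float | None = None
    n_subsamples: int = 130
    subsample_size: int = 1000
    alpha: float = 0.01
    correlation_method: str = "pearson"
    seed: int = 0
    correlation_pairs: list = field(default_factory=lambda: [
        ["lambda_oes", "lambda_edj"], ["lambda_oes", "delta"]])

    def validate(self) -> "AnalysisConfig":
        for width, rng, name in ((self.orientation_bin_width, 360.0, "orientation"),
                                 (self.inclination_bin_width, 180.0, "inclination")):
            if width <= 0 or abs(rng / width - round(rng / width)) > 1e-9:
                raise ValueError(f"{name} bin width must divide {rng}")
        if not 0 < self.relief_threshold < 180:
            raise ValueError("relief threshold must be inside (0, 180) deg")
        if self.min_patch_size < 1:
            raise ValueError("min_patch_size must be >= 1")
        if not 0 < self.crest_quantile < 1:
            raise ValueError("crest_quantile must be in (0, 1)")
        if self.target_face_count < 100:
            raise ValueError("target_face_count must be >= 100")
        if self.roi_mode not in ("auto", "landmarks", "z_cut", "none"):
            raise ValueError(f"unknown roi_mode {self.roi_mode!r}")
        if self.roi_mode == "z_cut" and self.roi_z_cut is None:
            raise ValueError("roi_mode 'z_cut' needs roi_z_cut")
        if self.n_subsamples < 1 or self.subsample_size < 3:
            raise ValueError("resampling sizes out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be pearson or spearman")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
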