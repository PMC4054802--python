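"""Flat pipeline configuration with validated defaults.

Every tunable of the pipeline lives here; the YAML on-disk form is a flat
key-value mapping and unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # skin pipeline
    downscale_factor: int = 8
    low_tail: float = 0.01
    high_tail: float = 0.01
    histogram_bins: int = 64
    smoothing_sigma: float = 2.0
    density_threshold: float = 0.1
    gmm_components: int = 5
    gmm_posterior_threshold: float = 0.5
    fusion_rule: str = "OR"
    border_enrichment_threshold: float = 1.0
    # complexion features
    lum_lo: float = 25.0
    lum_hi: float = 95.0
    lum_interval: float = 14.0
    include_base_bins: bool = True
    region_weights: tuple = (0.3, 0.3, 0.1, 0.1, 0.2)
    # fuzzy c-means
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    # SVM grid (exponents of 2)
    svm_c_exponents: tuple = tuple(range(-8, 16))
    svm_gamma_exponents: tuple = tuple(range(-8, 9))
    inner_folds: int = 5
    paper_protocol: bool = False
    # randomness
    master_seed: int = 0

    def __post_init__(self):
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be >= 1")
        if not 0 <= self.low_tail <= 0.2 or not 0 <= self.high_tail <= 0.2:
            raise ValueError("denoise tails must lie in [0, 0.2]")
        if abs(sum(self.region_weights) - 1.0) > 1e-6:
            raise ValueError("region_weights must sum to 1")
        if self.lum_hi <= self.lum_lo:
            raise ValueError("need lum_hi > lum_lo")
        if not self.fcm_m > 1:
            raise ValueError("fcm_m must be > 1")

    @property
    def binning(self):
        from .features import LuminanceBinning

        return LuminanceBinning(self.lum_lo, self.lum_hi, self.lum_interval)

    @property
    def detector_params(self):
        from .skin import SkinDetectorParams

        return SkinDetectorParams(
            histogram_bins=self.histogram_bins,
            smoothing_sigma=self.smoothing_sigma,
            density_threshold=self.density_threshold,
            gmm_components=self.gmm_components,
            gmm_posterior_threshold=self.gmm_posterior_threshold,
            fusion_rule=self.fusion_rule,
            border_enrichment_threshold=self.border_enrichment_threshold,
            seed=self.master_seed,
        )

    @property
    def c_grid(self):
        return [2.0**e for e in self.svm_c_exponents]

    @property
    def gamma_grid(self):
        return [2.0**e for e in self.svm_gamma_exponents]

    @property
    def region_weight_map(self):
        from .features import REGION_ORDER

        return dict(zip(REGION_ORDER, self.region_weights))

    def config_hash(self) -> str:
        """Stable short hash for run logging."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("region_weights", "svm_c_exponents", "svm_gamma_exponents"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
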