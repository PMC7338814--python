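"""Pipeline configuration: plain key=value files, strict validation.

Every tunable of the pipeline has a default here, so an empty config file
runs the full demo pipeline. Unknown keys and out-of-range values are
rejected by name; the effective configuration round-trips losslessly
through :func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .semiauto import SCANNER_THRESHOLDS

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # phantom
    grid_shape: tuple = (64, 64, 64)
    voxel_mm: tuple = (1.0, 1.0, 1.0)
    target_lesion_ml: float = 4.0
    lesion_contrast_t1: float = 0.80
    lesion_contrast_flair: float = 1.60
    bias_amplitude: float = 0.10
    noise_sd: float = 12.0
    atlas_smoothing_mm: float = 2.0
    # mixture / segmentation
    threshold: float | None = None  # None -> chi-square 0.95 quantile
    kappa_outlier: float = 10.0
    outlier_fraction: float = 0.01
    outlier_quantile: float = 0.95
    max_components_per_class: int = 2
    em_tol: float = 1e-5
    em_max_iter: int = 100
    bias_order: int = 3
    small_cluster_max: int = 60
    binarize_at: float = 0.5
    # protocol / consensus
    scanner: str = "Siemens"
    strict_gt: bool = False
    consensus_majority: int = 3
    seed_growth_connectivity: int = 6
    # evaluation / bullseye
    decomposition_connectivity: int = 18
    laplace_tol: float = 1e-5
    # reproducibility
    seed: int = 0

    def validate(self):
        if self.scanner not in SCANNER_THRESHOLDS:
            raise ValueError(
                f"scanner must be one of {sorted(SCANNER_THRESHOLDS)}, "
                f"got {self.scanner!r}"
            )
        if self.threshold is not None and not self.threshold > 0:
            raise ValueError("threshold must be positive (or unset)")
        if self.decomposition_connectivity not in (6, 18, 26):
            raise ValueError("decomposition_connectivity must be 6, 18 or 26")
        if self.seed_growth_connectivity not in (6, 18, 26):
            raise ValueError("seed_growth_connectivity must be 6, 18 or 26")
        if self.consensus_majority not in (2, 3, 4):
            raise ValueError("consensus_majority must be 2, 3 or 4")
        if not (0 < self.outlier_quantile < 1):
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.kappa_outlier <= 1:
            raise ValueError("kappa_outlier must exceed 1")
        if self.max_components_per_class < 1:
            raise ValueError("max_components_per_class must be >= 1")
        if self.target_lesion_ml < 0 or self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("phantom amplitudes must be nonnegative")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_mm"] = list(self.voxel_mm)
        return d

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _parse_value(name, raw):
    raw = raw.strip()
    try:
        val = json.loads(raw)
    except json.JSONDecodeError:
        val = raw  # bare string
    if name in ("grid_shape", "voxel_mm"):
        if not isinstance(val, list) or len(val) != 3:
            raise ValueError(f"{name} must be a JSON list of 3 values: {raw!r}")
        return tuple(val)
    return val


def load_config(path=None, text=None) -> PipelineConfig:
    """Read a `key = value` config file (values in JSON syntax; '#' comments).

    Unknown keys raise; missing keys take their defaults.
    """
    if text is None:
        with open(path) as fh:
            text = fh.read()
    overrides = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELDS:
            raise ValueError(f"unknown config key {key!r} (line {lineno})")
        overrides[key] = _parse_value(key, raw)
    return PipelineConfig(**overrides).validate()


def save_config(config: PipelineConfig, path):
    with open(path, "w") as fh:
        for key, val in config.to_dict().items():
            fh.write(f"{key} = {json.dumps(val)}\n")
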