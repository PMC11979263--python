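"""YAML-backed pipeline configuration with schema validation.

One global seed governs every random stage; stage seeds are derived from it
deterministically, so a config reproduces a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .autoencoder import ARCHITECTURES

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # paths
    out_dir: str = "stenograde_run"
    manifest: str | None = None  # None -> synthesize a cohort
    # synthetic cohort
    n_patients: int = 60
    image_rows: int = 900
    missing_view_rate: float = 0.06
    # roi
    roi_rows: int = 854
    # radiomics
    n_bins: int = 25
    wavelet: str = "coif1"
    # autoencoder
    ae_architecture: str = "AE64"
    ae_epochs: int = 300
    ae_batch_size: int = 48
    ae_learning_rate: float = 0.001
    # selection
    rho_max: float = 0.95
    alpha: float = 0.05
    # cascade
    n_trees: int = 500
    # splits
    test_fraction: float = 0.15
    inner_repeats: int = 30
    inner_val_fraction: float = 0.20
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ae_architecture not in ARCHITECTURES:
            raise ValueError(
                f"ae_architecture must be one of {sorted(ARCHITECTURES)}"
            )
        for name in ("missing_view_rate", "test_fraction", "inner_val_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 < self.rho_max <= 1.0) or not (0.0 < self.alpha < 1.0):
            raise ValueError("rho_max must be in (0, 1] and alpha in (0, 1)")
        for name in ("n_patients", "image_rows", "roi_rows", "n_bins", "ae_epochs",
                     "ae_batch_size", "n_trees", "inner_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the full configuration, embedded in run metadata."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
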