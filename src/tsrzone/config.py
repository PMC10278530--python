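"""Pipeline configuration with file/flag merging.

Precedence: explicit keyword overrides > config file values > defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .segmentation import DEFAULT_DAB_THRESHOLD, PixelClassifier


@dataclass
class PipelineConfig:
    mpp_override: float | None = None
    band_width_um: float = 1000.0
    field_dims_um: tuple[float, float] = (1150.0, 680.0)
    n_fields: int = 3
    tsr_threshold: float = 50.0
    stride_um: float = 50.0
    border_margin_um: float = 20.0
    seed: int = 0
    segmentation_mode: str = "threshold"  # threshold | trained
    dab_threshold: float = DEFAULT_DAB_THRESHOLD
    classifier: PixelClassifier | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.field_dims_um = tuple(self.field_dims_um)
        for name in ("band_width_um", "stride_um", "border_margin_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(d <= 0 for d in self.field_dims_um):
            raise ValueError("field dimensions must be > 0")
        if not 0 < self.tsr_threshold < 100:
            raise ValueError("tsr_threshold must lie in (0, 100)")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.mpp_override is not None and self.mpp_override <= 0:
            raise ValueError("mpp_override must be > 0")
        if self.segmentation_mode not in ("threshold", "trained"):
            raise ValueError("segmentation_mode must be 'threshold' or 'trained'")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Build a config from an optional JSON file plus keyword overrides."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                values.update(json.load(fh))
        known = {f.name for f in dc_fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
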