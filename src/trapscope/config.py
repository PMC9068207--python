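"""Run configuration: validated settings, YAML round-trip, provenance dump."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """All knobs of the quantification pipeline in one validated record.

    A serialized copy is written next to every result so a run can be
    reproduced exactly from its output directory.
    """

    inputs: list[str] = field(default_factory=list)
    channel_a: str = "CD8"
    channel_b: str = "NPM"
    channel_names: list[str] | None = None
    pixel_size_um: float = 0.5
    psf_sigma_um: float = 0.5
    standardize: bool = True         # resample + blur-match before analysis
    working_pixel_um: float = 0.25
    analysis_sigma_um: float = 1.0
    n_scales: int | None = None      # None: largest feasible (capped at 6)
    k: float = 3.0
    scales_used: list[int] | None = None  # None: physical-band auto-selection
    min_area_um2: float = 20.0
    max_gap_um: float = 1.0
    field_size_um: float = 40.0
    n_fields: int = 5
    permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "trapscope_out"

    def validate(self) -> "RunConfig":
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.k <= 0:
            raise ValidationError("k must be > 0")
        if self.min_area_um2 < 0:
            raise ValidationError("min_area_um2 must be >= 0")
        if self.max_gap_um < 0:
            raise ValidationError("max_gap_um must be >= 0")
        if self.n_scales is not None and self.n_scales < 1:
            raise ValidationError("n_scales must be >= 1")
        if self.n_fields < 1:
            raise ValidationError("n_fields must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.permutations < 100:
            raise ValidationError("permutations must be >= 100")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
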