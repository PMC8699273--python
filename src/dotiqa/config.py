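"""Single study configuration object, serializable to YAML.

A stored config plus the master seed reproduces every stage output
byte-for-byte; each stage writes a manifest carrying the config hash so any
output file can be traced back to the settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .forward_model import FDSettings
from .inverse_solver import GaussNewtonConfig
from .metrics import SSIMConfig

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """All knobs of the simulation/reconstruction/assessment pipeline."""

    # meshes: centre-fan counts, 1:4 refinement levels, disc radius (mm)
    forward_fan: int = 8
    forward_levels: int = 5
    inverse_fan: int = 6
    inverse_levels: int = 4
    radius_mm: float = 40.0
    # optodes
    n_sources: int = 16
    n_detectors: int = 16
    source_start_angle: float = 0.0
    # stages
    fd: FDSettings = field(default_factory=FDSettings)
    gauss_newton: GaussNewtonConfig = field(default_factory=GaussNewtonConfig)
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    grid_size: int = 160
    # study grid
    cases: tuple = ("B1", "B2")
    noises: tuple = ("1pct", "10pct")
    n_subjects: int = 20
    master_seed: int = 12345

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cases"] = list(self.cases)
        d["noises"] = list(self.noises)
        d["ssim"]["scale_weights"] = list(self.ssim.scale_weights)
        d["gauss_newton"]["clip_range"] = list(self.gauss_newton.clip_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, sub in (("fd", FDSettings),
                         ("gauss_newton", GaussNewtonConfig),
                         ("ssim", SSIMConfig)):
            if key in d and isinstance(d[key], dict):
                sd = dict(d[key])
                if key == "ssim" and "scale_weights" in sd:
                    sd["scale_weights"] = tuple(sd["scale_weights"])
                if key == "gauss_newton" and "clip_range" in sd:
                    sd["clip_range"] = tuple(sd["clip_range"])
                d[key] = sub(**sd)
        for key in ("cases", "noises"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
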