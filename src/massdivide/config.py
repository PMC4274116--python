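"""Pipeline configuration: one validated object driving every stage.

All randomness in the package (synthetic movies, classifier training splits)
flows from the single ``seed`` here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .division import DivisionParams
from .segment import SegmentationConfig
from .synthetic import ALPHA_DEFAULT, WAVELENGTH_DEFAULT


@dataclass
class PipelineConfig:
    """End-to-end settings for the analysis pipeline."""

    pixel_size: float = 1.0            # um/px
    wavelength: float = WAVELENGTH_DEFAULT   # nm
    frame_interval: float = 3.0        # min
    alpha: float = ALPHA_DEFAULT       # m^3/kg
    adherent: bool = True
    seed: int = 0
    max_disp: float = 20.0             # um/frame tracking gate
    walker_beta: float = 130.0         # random-walker edge-weight parameter
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    division: DivisionParams = field(default_factory=DivisionParams)

    def __post_init__(self):
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationConfig(**self.segmentation)
        if isinstance(self.division, dict):
            d = dict(self.division)
            for k in ("daughter_mass_window", "combined_mass_window"):
                if k in d:
                    d[k] = tuple(d[k])
            self.division = DivisionParams(**d)
        self.validate()

    def validate(self) -> None:
        for name in ("pixel_size", "wavelength", "frame_interval",
                     "alpha", "max_disp", "walker_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # keep the geometry consistent between config and segmentation
        self.segmentation.pixel_size = self.pixel_size
        self.segmentation.alpha = self.alpha

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()
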