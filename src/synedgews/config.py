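"""Acquisition and run configuration.

All physical quantities carry explicit units.  The sample-plane pixel size
``s = camera_pixel_size_um * binning / magnification`` converts the expected
punctum diameter range (µm) into the pixel-area gate used by every segmenter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


class ParameterError(ValueError):
    """Raised when a configuration or call parameter violates its contract."""


@dataclass
class AcquisitionConfig:
    """Optical and algorithmic parameters of one acquisition setup.

    Parameters
    ----------
    camera_pixel_size_um : float
        Physical size of one camera pixel in µm.
    magnification : float
        Total optical magnification (dimensionless, > 0).
    binning : int
        On-camera binning factor (1 = none).
    min_diameter_um, max_diameter_um : float
        Expected punctum diameter bounds in µm; converted to a pixel-area
        range by :func:`synedgews.segment.compute_size_range`.
    n_iterations : int
        Number of gradient-threshold iterations of the edge/watershed
        segmenter.  More iterations trade specificity for sensitivity.
    retouch_enabled : bool
        Replace very bright regions (somata) by background before
        subtraction.
    bleach_correct_enabled : bool
        Divide traces by a monoexponential decay fitted on baseline frames.
    gradient_quantile_start : float
        Quantile of the nonzero gradient magnitudes defining the first
        gradient threshold.
    gradient_decay : float
        Geometric decay factor applied to the gradient threshold per
        iteration.
    """

    camera_pixel_size_um: float = 8.0
    magnification: float = 60.0
    binning: int = 2
    min_diameter_um: float = 0.8
    max_diameter_um: float = 3.2
    n_iterations: int = 2
    retouch_enabled: bool = False
    bleach_correct_enabled: bool = False
    gradient_quantile_start: float = 0.985
    gradient_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.camera_pixel_size_um <= 0:
            raise ParameterError("camera_pixel_size_um must be positive")
        if self.magnification <= 0:
            raise ParameterError("magnification must be positive")
        if int(self.binning) != self.binning or self.binning < 1:
            raise ParameterError("binning must be a positive integer")
        if self.min_diameter_um <= 0 or self.max_diameter_um <= 0:
            raise ParameterError("diameter bounds must be positive")
        if self.min_diameter_um >= self.max_diameter_um:
            raise ParameterError("min_diameter_um must be < max_diameter_um")
        if int(self.n_iterations) != self.n_iterations or self.n_iterations < 1:
            raise ParameterError("n_iterations must be a positive integer")
        if not 0 < self.gradient_quantile_start < 1:
            raise ParameterError("gradient_quantile_start must be in (0, 1)")
        if not 0 < self.gradient_decay < 1:
            raise ParameterError("gradient_decay must be in (0, 1)")

    @property
    def pixel_size_um(self) -> float:
        """Sample-plane size of one image pixel in µm."""
        return self.camera_pixel_size_um * self.binning / self.magnification

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """Full configuration of one batch run: acquisition + routine knobs.

    Serializes losslessly to YAML and is echoed into every output directory
    so a run can be reproduced bit-identically.
    """

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    algorithm: str = "synedgews"            # synedgews | thr | thrws | locmax
    smoothing_window: int = 3               # frames; 1 disables smoothing
    bf_tolerance_px: float = 2.0
    template_selection: Tuple[int, int] = (0, 1)   # [start, stop) frame range
    baseline_frames: Tuple[int, int] = (0, 20)
    nh4cl_frames: Tuple[int, int] = (240, 260)
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.acquisition, dict):
            self.acquisition = AcquisitionConfig(**self.acquisition)
        if self.algorithm not in ("synedgews", "thr", "thrws", "locmax"):
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        if self.smoothing_window < 1:
            raise ParameterError("smoothing_window must be >= 1")
        if self.bf_tolerance_px <= 0:
            raise ParameterError("bf_tolerance_px must be positive")
        for name in ("template_selection", "baseline_frames", "nh4cl_frames"):
            rng = tuple(getattr(self, name))
            if len(rng) != 2 or rng[0] < 0 or rng[1] <= rng[0]:
                raise ParameterError(f"{name} must be a (start, stop) range with stop > start >= 0")
            setattr(self, name, rng)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("template_selection", "baseline_frames", "nh4cl_frames"):
            d[name] = list(d[name])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
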