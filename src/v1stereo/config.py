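"""Run configuration: filter bank, hypothesis set, pooling and metric options.

A :class:`RunConfig` captures every tunable of a disparity-estimation run so
that results are reproducible from the record alone.  Defaults follow the
synthetic-stereogram protocol: a 6-orientation x 4-scale log-Gabor bank
(lambda_min 3 px, scale factor 1.6, sigma_r/f0 = 0.65), disparity
hypotheses -6..+6 px chosen so the stimulus range (+-5 px) stays interior
to the search, a 0.25 px bad-pixel threshold, and a 13 px evaluation border
(the largest filter wavelength, rounded up).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml

from .evaluation import DEFAULT_BORDER_PX, DEFAULT_THRESHOLD_PX
from .filterbank import (DEFAULT_ANGULAR_SIGMA_RAD, FAMILIES,
                         GABOR_FREQUENCIES_CPD, FilterBank, make_filter_bank)
from .search import DisparityHypothesisSet


@dataclass(frozen=True)
class RunConfig:
    family: str = "log_gabor"
    orientations_deg: tuple[float, ...] | None = None  # None -> family default
    n_scales: int = 4
    lambda_min_px: float = 3.0
    scale_factor: float = 1.6
    sigma_ratio: float = 0.65
    angular_sigma_rad: float = DEFAULT_ANGULAR_SIGMA_RAD
    pixels_per_degree: float = 12.0
    gabor_frequencies_cpd: tuple[float, ...] = GABOR_FREQUENCIES_CPD
    disparity_min: float = -6.0
    disparity_max: float = 6.0
    disparity_step: float = 1.0
    pooling_method: str = "iterative"
    dot_density: float = 0.5
    border_px: int = DEFAULT_BORDER_PX
    bad_pixel_threshold: float = DEFAULT_THRESHOLD_PX
    rf_window: tuple[int, int] | None = None  # e.g. (49, 97) spatial truncation
    energy_smoothing_px: int = 0  # optional box smoothing of energy maps, off

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.disparity_step <= 0:
            raise ValueError("disparity_step must be positive")
        if self.disparity_max < self.disparity_min:
            raise ValueError("disparity_max must be >= disparity_min")
        if not 0.0 < self.dot_density < 1.0:
            raise ValueError("dot_density must be in (0, 1)")

    # -- derived objects ----------------------------------------------------
    def make_bank(self) -> FilterBank:
        return make_filter_bank(
            family=self.family, orientations_deg=self.orientations_deg,
            n_scales=self.n_scales, lambda_min_px=self.lambda_min_px,
            scale_factor=self.scale_factor, sigma_ratio=self.sigma_ratio,
            angular_sigma_rad=self.angular_sigma_rad,
            pixels_per_degree=self.pixels_per_degree,
            gabor_frequencies_cpd=self.gabor_frequencies_cpd)

    def hypotheses(self) -> DisparityHypothesisSet:
        return DisparityHypothesisSet.from_range(
            self.disparity_min, self.disparity_max, self.disparity_step)

    def for_kind(self, kind: str) -> "RunConfig":
        """Kind-appropriate hypothesis step: 1.0 px for the square
        stereogram, 0.25 px for ramp and Gabor-surface stereograms."""
        step = 1.0 if kind in ("square", "uniform") else 0.25
        return replace(self, disparity_step=step)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("orientations_deg", "gabor_frequencies_cpd", "rf_window"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key in ("orientations_deg", "gabor_frequencies_cpd", "rf_window"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
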