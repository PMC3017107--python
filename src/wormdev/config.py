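"""Configuration objects shared across the pipeline.

All lengths are stored in millimetres internally; the worm body radius of
50 µm is therefore 0.05 mm. Times are minutes post-fertilization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

DEFAULT_STAGE_TIMES: tuple[float, ...] = (350.0, 400.0, 500.0, 800.0, 2000.0, 2700.0)
DEFAULT_HATCH_TIME: float = 840.0
DEFAULT_BODY_RADIUS_MM: float = 0.05


@dataclass(frozen=True)
class SpatialConfig:
    """Geometry and staging parameters of the worm body model.

    Parameters
    ----------
    body_radius : float
        Radius of the cylindrical body model in mm (assumed constant along
        the anterior-posterior axis). Default 0.05 mm (50 µm).
    hatch_time : float
        Approximate hatching time in minutes post-fertilization; divides
        births into embryonic and post-embryonic phases. Default 840.
    stage_times : tuple of float
        Ordered developmental cutoff times (minutes) at which staged
        networks are constructed.
    """

    body_radius: float = DEFAULT_BODY_RADIUS_MM
    hatch_time: float = DEFAULT_HATCH_TIME
    stage_times: tuple[float, ...] = DEFAULT_STAGE_TIMES

    def __post_init__(self) -> None:
        if not self.body_radius > 0:
            raise ValueError(f"body_radius must be positive, got {self.body_radius}")
        if not self.hatch_time > 0:
            raise ValueError(f"hatch_time must be positive, got {self.hatch_time}")
        times = tuple(float(t) for t in self.stage_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"stage_times must be strictly increasing, got {times}")
        object.__setattr__(self, "stage_times", times)


@dataclass(frozen=True)
class LengthClassifier:
    """Ten-bin connection-length classification.

    Lengths are split into ``n_bins`` bins of ``bin_width`` mm; the first
    ``short_bins`` bins are short-range, the last ``long_bins`` bins are
    long-range, everything between is medium-range. With the defaults the
    derived thresholds are short < 0.36 mm and long >= 0.84 mm.

    Boundary convention: bins are half-open [lo, hi), so a length of
    exactly 0.84 mm is long. Lengths beyond ``n_bins * bin_width`` are
    still long (the classifier is total).
    """

    n_bins: int = 10
    bin_width: float = 0.12
    short_bins: int = 3
    long_bins: int = 3

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.bin_width <= 0:
            raise ValueError("n_bins must be >= 1 and bin_width positive")
        if self.short_bins + self.long_bins >= self.n_bins:
            raise ValueError(
                "short_bins + long_bins must be smaller than n_bins "
                f"(got {self.short_bins} + {self.long_bins} >= {self.n_bins})"
            )

    @property
    def short_max(self) -> float:
        """Upper (exclusive) bound of the short class in mm."""
        return self.short_bins * self.bin_width

    @property
    def long_min(self) -> float:
        """Lower (inclusive) bound of the long class in mm."""
        return (self.n_bins - self.long_bins) * self.bin_width
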