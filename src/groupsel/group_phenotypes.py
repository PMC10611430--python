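"""Group-level phenotype statistics: settling rate, flocculation, mean size.

Settling rate is estimated from a grayscale video of a population
sedimenting in a back-lit cuvette, as the rate of displacement of the
intensity-weighted biomass centroid. Flocculation efficiency is the
coefficient of variation of pixel intensity in a single well-mixed frame:
biomass concentrated in flocs makes the image heterogeneous. The
biomass-weighted mean group size is the size-biased mean of a per-group size
sample (e.g. flow-cytometry forward scatter), computed over 100 bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "VideoStack",
    "FscSample",
    "NoBiomassError",
    "UndefinedStatisticError",
    "settling_rate",
    "flocculation_efficiency",
    "biomass_weighted_mean_size",
]


class NoBiomassError(ValueError):
    """Raised when a video contains no detectable biomass."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class VideoStack:
    """Ordered grayscale frames with a frame interval and optional scale."""

    frames: np.ndarray  # (n_frames, height, width), intensities >= 0
    frame_interval: float = 1.0
    pixel_scale: float | None = None  # length per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (n_frames >= 2, height, width)")
        if not np.isfinite(self.frames).all() or (self.frames < 0).any():
            raise ValueError("intensities must be finite and >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.frames.astype(np.float32))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        frame_interval: float = 1.0,
        pixel_scale: float | None = None,
    ) -> "VideoStack":
        import tifffile

        return cls(
            frames=tifffile.imread(str(path)).astype(float),
            frame_interval=frame_interval,
            pixel_scale=pixel_scale,
        )


@dataclass(frozen=True)
class FscSample:
    """Per-group size values (forward-scatter proxy for cluster size)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("sample must be non-empty")
        if not np.isfinite(self.values).all() or (self.values <= 0).any():
            raise ValueError("all size values must be positive and finite")


def settling_rate(video: VideoStack, foreground: str = "otsu") -> float:
    """Biomass-displacement settling rate from a video stack.

    For each frame the intensity-weighted vertical centroid of the biomass is
    computed, and its least-squares slope against time is returned (positive
    slopes point down the frame; pixels/second, or length/second when the
    stack carries a ``pixel_scale``). Static illumination structure is
    removed by subtracting each column's minimum over the whole stack;
    ``foreground="otsu"`` additionally masks the frames at an Otsu threshold
    so that diffuse sensor noise does not dilute the centroid, while
    ``foreground="none"`` uses all background-subtracted intensity.
    """
    if foreground not in ("otsu", "none"):
        raise ValueError("foreground must be 'otsu' or 'none'")
    frames = video.frames - video.frames.min(axis=(0, 1), keepdims=True)
    if frames.max() <= 0:
        raise NoBiomassError("no biomass detected after background subtraction")
    if foreground == "otsu" and np.ptp(frames) > 0:
        thr = threshold_otsu(frames.ravel())
        frames = np.where(frames > thr, frames, 0.0)
        if frames.max() <= 0:
            raise NoBiomassError("no biomass above the foreground threshold")
    totals = frames.sum(axis=(1, 2))
    if (totals <= 0).any():
        raise NoBiomassError("a frame contains no biomass")
    rows = np.arange(frames.shape[1], dtype=float)
    centroids = (frames.sum(axis=2) * rows).sum(axis=1) / totals
    times = np.arange(video.n_frames) * video.frame_interval
    slope = float(np.polyfit(times, centroids, 1)[0])
    if video.pixel_scale is not None:
        slope *= video.pixel_scale
    return slope


def flocculation_efficiency(frame: np.ndarray, statistic: str = "cv") -> float:
    """Heterogeneity of pixel intensity in a well-mixed frame.

    The primary statistic is the coefficient of variation (SD/mean), which is
    invariant to the illumination scale; ``statistic="variance"`` exposes the
    raw pixel-intensity variance instead.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or not np.isfinite(frame).all():
        raise ValueError("frame must be non-empty and finite")
    if statistic not in ("cv", "variance"):
        raise ValueError("statistic must be 'cv' or 'variance'")
    if statistic == "variance":
        return float(frame.var())
    mean = frame.mean()
    if mean == 0:
        raise UndefinedStatisticError("coefficient of variation undefined at zero mean")
    return float(frame.std() / mean)


def biomass_weighted_mean_size(sample: FscSample, n_bins: int = 100) -> float:
    """Size-biased mean group size, binned by biomass.

    The size range is split into ``n_bins`` equal-width bins; each bin is
    assigned the fraction of total biomass it holds (sum of member sizes over
    the grand sum) and represented by its center. The result is the
    biomass-fraction-weighted mean of the bin centers, and always dominates
    the ordinary arithmetic mean of the sample.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = sample.values
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return lo
    biomass, edges = np.histogram(v, bins=n_bins, range=(lo, hi), weights=v)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float((biomass * centers).sum() / v.sum())
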