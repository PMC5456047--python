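"""Shared containers and error types.

The whole pipeline moves data around as uniformly sampled scalar time
series (movement displacement at 6 Hz, estimated syllable rate at 3 Hz),
frame stacks, and rectangular regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DyadsyncError(Exception):
    """Base class for all package errors."""


class ParameterError(DyadsyncError, ValueError):
    """A parameter violates its documented range or invariant."""


class InputError(DyadsyncError, ValueError):
    """An input object is unusable (empty, too short, mismatched)."""


class GeometryError(DyadsyncError, ValueError):
    """A region of interest does not fit inside the frame."""


class RateMismatchError(DyadsyncError, ValueError):
    """Two series that must share a sampling rate do not."""


class CoverageError(DyadsyncError, ValueError):
    """A requested span or lag range is not covered by the data."""


class NormalizationError(DyadsyncError, ValueError):
    """z-scoring was requested on a zero-variance series."""


class CalibrationError(DyadsyncError, RuntimeError):
    """A radius calibration target could not be attained."""


class InfeasiblePairingError(DyadsyncError, ValueError):
    """A virtual-pair plan cannot be constructed (too few dyads)."""


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : array of float
        Sample values.  Must be finite.
    rate_hz : float
        Sampling rate in samples per second (> 0).
    t0 : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate_hz <= 0:
            raise ParameterError(f"rate_hz must be > 0, got {self.rate_hz}")
        if self.values.ndim != 1:
            raise InputError("series values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise InputError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate_hz

    def truncated(self, n: int) -> "UniformSeries":
        """Right-truncate to the first ``n`` samples."""
        return UniformSeries(self.values[:n], self.rate_hz, self.t0)


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular pixel region, half-open: [x0, x1) x [y0, y1), 0-based."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise GeometryError(f"degenerate ROI {self.label}: "
                                f"({self.x0},{self.y0})-({self.x1},{self.y1})")
        if min(self.x0, self.y0) < 0:
            raise GeometryError(f"ROI {self.label} has negative coordinates")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def validate_for(self, height: int, width: int) -> None:
        if self.x1 > width or self.y1 > height:
            raise GeometryError(
                f"ROI {self.label} ({self.x0},{self.y0})-({self.x1},{self.y1}) "
                f"exceeds frame bounds {width}x{height}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of RGB video frames.

    ``frames`` has shape (n_frames, height, width, 3), integer dtype with
    values in [0, 255]; ``fps`` is the nominal capture rate.
    """

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise InputError("frames must have shape (n, H, W, 3)")
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
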