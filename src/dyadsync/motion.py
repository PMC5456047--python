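"""Motion-energy extraction by frame differencing.

A participant's continuous movement-displacement signal is obtained from
video by comparing every ``frame_step``-th frame inside a region of
interest and summing the absolute RGB change (or counting changed
pixels).  At the nominal 30 fps with the default step of 5 this yields a
6 Hz displacement series per region.

Differences are computed on raw integer RGB values without a luminance
collapse, summed over the three channels.  No detrending or
normalization happens here; windowed correlation downstream z-scores
per window.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .core import FrameStack, InputError, ParameterError, RegionSpec, UniformSeries

__all__ = [
    "frame_difference_series",
    "read_frame_directory",
    "read_roi_csv",
    "write_series_csv",
    "read_series_csv",
]


def frame_difference_series(
    stack: FrameStack,
    roi: RegionSpec,
    frame_step: int = 5,
    mode: Literal["sum_abs", "count_changed"] = "sum_abs",
    change_threshold: int = 10,
) -> UniformSeries:
    """Convert a frame stack to a movement-displacement series inside ``roi``.

    Sample ``i`` (i >= 1) compares frames ``i*frame_step`` and
    ``(i-1)*frame_step``:

    - ``sum_abs``: sum over ROI pixels and RGB channels of the absolute
      intensity difference;
    - ``count_changed``: number of ROI pixels whose largest per-channel
      absolute difference exceeds ``change_threshold``.

    Returns a :class:`UniformSeries` at ``fps / frame_step`` Hz whose
    first sample sits at ``t0 = frame_step / fps``.  Output length is
    ``floor((n_frames - 1) / frame_step)``.
    """
    if frame_step <= 0:
        raise ParameterError(f"frame_step must be positive, got {frame_step}")
    n = len(stack)
    if n == 0:
        raise InputError("empty frame stack")
    if n <= frame_step:
        raise InputError(
            f"need more than frame_step={frame_step} frames, got {n}")
    if mode not in ("sum_abs", "count_changed"):
        raise ParameterError(f"unknown mode {mode!r}")
    h, w = stack.shape
    roi.validate_for(h, w)

    ys, xs = roi.slices()
    sampled = stack.frames[::frame_step, ys, xs, :].astype(np.int64)
    diff = np.abs(sampled[1:] - sampled[:-1])
    if mode == "sum_abs":
        values = diff.sum(axis=(1, 2, 3)).astype(float)
    else:
        values = (diff.max(axis=3) > change_threshold).sum(axis=(1, 2)).astype(float)

    n_out = (n - 1) // frame_step
    values = values[:n_out]
    rate = stack.fps / frame_step
    return UniformSeries(values, rate_hz=rate, t0=frame_step / stack.fps)


def read_frame_directory(path: str | Path, fps: float = 30.0) -> FrameStack:
    """Load a numbered PNG/JPEG frame sequence as a :class:`FrameStack`.

    Files are sorted by name; grayscale images are broadcast to RGB.
    """
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise InputError(f"no PNG/JPEG frames found in {path}")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(img[..., :3])
    return FrameStack(np.stack(frames), fps=fps)


def read_roi_csv(path: str | Path) -> list[RegionSpec]:
    """Read ROI definitions from a CSV with columns label,x0,y0,x1,y1."""
    df = pd.read_csv(path)
    required = {"label", "x0", "y0", "x1", "y1"}
    if not required.issubset(df.columns):
        raise InputError(f"ROI file must have columns {sorted(required)}")
    return [RegionSpec(str(r.label), int(r.x0), int(r.y0), int(r.x1), int(r.y1))
            for r in df.itertuples()]


def write_series_csv(series: UniformSeries, path: str | Path) -> None:
    """Write a series as a two-column CSV (t_s, value)."""
    pd.DataFrame({"t_s": series.times, "value": series.values}).to_csv(
        path, index=False)


def read_series_csv(path: str | Path) -> UniformSeries:
    """Read a series written by :func:`write_series_csv`."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise InputError("series CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InputError("series CSV is not uniformly sampled")
    return UniformSeries(df["value"].to_numpy(float), rate_hz=1.0 / dt[0], t0=t[0])
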