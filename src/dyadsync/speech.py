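"""Speech-rate time series from utterance tiers and syllable onsets.

Syllable nuclei are approximated by voiced intensity peaks inside tagged
utterance intervals (a standard nucleus-detection scheme: a candidate
peak counts only if it is separated from its accepted neighbour by an
intensity dip of at least ``min_dip_db`` and by at least
``min_separation_s``).  Onset events are then converted to a continuous
estimated-syllable-rate series by counting onsets in 5-second windows
slid by 333 ms, scaled by 20, giving a 3 Hz series per speaker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import CoverageError, InputError, ParameterError, UniformSeries
from .textgrid import read_textgrid, write_textgrid

__all__ = [
    "UtteranceTier", "EventTimes", "ProsodyContour",
    "detect_syllable_onsets", "rate_series",
    "read_utterance_tier", "write_utterance_tier",
]


@dataclass(frozen=True)
class UtteranceTier:
    """Per-speaker utterance intervals [start_s, end_s), sorted, disjoint."""

    speaker_id: str
    intervals: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        iv = np.atleast_2d(np.asarray(self.intervals, dtype=float))
        if iv.size == 0:
            iv = np.empty((0, 2))
        if iv.shape[1] != 2:
            raise InputError("intervals must be (n, 2)")
        if iv.size and (np.any(iv[:, 0] >= iv[:, 1]) or np.any(iv < 0)):
            raise InputError("intervals must satisfy 0 <= start < end")
        if iv.shape[0] > 1 and np.any(iv[1:, 0] < iv[:-1, 1] - 1e-12):
            raise InputError(f"overlapping intervals for speaker {self.speaker_id}")
        object.__setattr__(self, "intervals", iv)

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any utterance interval."""
        t = np.asarray(t, dtype=float)
        inside = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            inside |= (t >= a) & (t < b)
        return inside

    @property
    def total_speaking_s(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))


@dataclass(frozen=True)
class EventTimes:
    """Sorted syllable-onset times for one speaker."""

    speaker_id: str
    onsets_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.onsets_s, dtype=float).ravel()
        if t.size and np.any(np.diff(t) <= 0):
            raise InputError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets_s", t)

    def __len__(self) -> int:
        return len(self.onsets_s)

    def shifted(self, delta: float) -> "EventTimes":
        return EventTimes(self.speaker_id, self.onsets_s + delta)


@dataclass(frozen=True)
class ProsodyContour:
    """Uniformly gridded intensity (dB) and voicing for one channel."""

    times_s: np.ndarray
    intensity_db: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensity_db, dtype=float)
        v = np.asarray(self.voiced, dtype=bool)
        if t.size == 0:
            raise InputError("empty prosody contour")
        if not (len(t) == len(y) == len(v)):
            raise InputError("contour arrays must share length")
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InputError("contour grid must be uniform")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensity_db", y)
        object.__setattr__(self, "voiced", v)


def detect_syllable_onsets(
    contour: ProsodyContour,
    tier: UtteranceTier,
    min_dip_db: float = 2.0,
    min_separation_s: float = 0.1,
) -> EventTimes:
    """Pick voiced intensity peaks inside utterances as syllable onsets.

    Candidate local maxima are gated to voiced samples inside an
    utterance interval, then accepted greedily in time order: a new peak
    qualifies only if the intensity valley between it and the previously
    accepted peak is at least ``min_dip_db`` below both, and the peaks
    are at least ``min_separation_s`` apart.  When the dip or separation
    test fails, the higher of the two competing peaks is retained.
    """
    t, y = contour.times_s, contour.intensity_db
    if tier.intervals.size:
        lo, hi = tier.intervals[0, 0], tier.intervals[-1, 1]
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise CoverageError("contour does not cover the utterance tier span")

    peaks, _ = find_peaks(y)
    eligible = contour.voiced[peaks] & tier.contains(t[peaks])
    candidates = peaks[eligible]

    kept: list[int] = []
    for idx in candidates:
        if not kept:
            kept.append(int(idx))
            continue
        prev = kept[-1]
        valley = float(np.min(y[prev:idx + 1]))
        deep_enough = (y[idx] - valley >= min_dip_db
                       and y[prev] - valley >= min_dip_db)
        far_enough = (t[idx] - t[prev]) >= min_separation_s
        if deep_enough and far_enough:
            kept.append(int(idx))
        elif y[idx] > y[prev]:
            kept[-1] = int(idx)
    return EventTimes(tier.speaker_id, t[np.asarray(kept, dtype=int)])


def rate_series(
    events: EventTimes,
    span_s: tuple[float, float],
    window_s: float = 5.0,
    slide_s: float = 1.0 / 3.0,
    scale: float = 20.0,
) -> UniformSeries:
    """Estimated-syllable-rate series from onset events.

    The value of the window starting at ``t`` is ``scale`` times the
    number of onsets in the half-open window [t, t + window_s).  Windows
    are left-aligned and only windows fully inside ``span_s`` are
    emitted, so the output rate is ``1 / slide_s`` (3 Hz by default).

    The default ``scale=20`` follows the source convention of
    multiplying the 5-second count by 20; downstream coordination
    metrics z-score the series, making them invariant to this affine
    factor.
    """
    t_start, t_end = span_s
    if window_s <= 0 or slide_s <= 0:
        raise ParameterError("window_s and slide_s must be positive")
    if t_end - t_start < window_s:
        raise InputError("span shorter than one window")

    n_windows = int(np.floor((t_end - t_start - window_s) / slide_s + 1e-9)) + 1
    starts = t_start + np.arange(n_windows) * slide_s
    onsets = events.onsets_s
    counts = (np.searchsorted(onsets, starts + window_s, side="left")
              - np.searchsorted(onsets, starts, side="left"))
    return UniformSeries(scale * counts.astype(float),
                         rate_hz=1.0 / slide_s, t0=t_start)


def read_utterance_tier(path: str | Path, speaker_id: str | None = None,
                        tier_name: str | None = None) -> UtteranceTier:
    """Read one speaker's utterance intervals from a TextGrid or CSV.

    TextGrid: non-empty-text intervals of the named tier (default: the
    tier matching ``speaker_id``, else the only tier).  CSV: columns
    speaker,start_s,end_s filtered to ``speaker_id`` when given.
    """
    path = Path(path)
    if path.suffix.lower() == ".textgrid" or path.suffix == ".tg":
        tiers = read_textgrid(path)
        name = tier_name or speaker_id
        if name is None:
            if len(tiers) != 1:
                raise InputError(
                    f"{path} has tiers {sorted(tiers)}; specify one")
            name = next(iter(tiers))
        if name not in tiers:
            raise InputError(f"tier {name!r} not in {path}")
        iv = [(a, b) for a, b, text in tiers[name] if text.strip()]
        return UtteranceTier(name, np.asarray(iv, dtype=float).reshape(-1, 2))
    df = pd.read_csv(path)
    if speaker_id is not None:
        df = df[df["speaker"].astype(str) == str(speaker_id)]
    return UtteranceTier(str(speaker_id or "speaker"),
                         df[["start_s", "end_s"]].to_numpy(float))


def write_utterance_tier(tiers: list[UtteranceTier], path: str | Path,
                         xmax: float | None = None) -> None:
    """Write speakers' utterance tiers to a long-format TextGrid."""
    write_textgrid(
        {t.speaker_id: [(a, b, "speech") for a, b in t.intervals]
         for t in tiers},
        path, xmin=0.0, xmax=xmax)
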