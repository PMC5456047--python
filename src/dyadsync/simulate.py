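"""Synthetic dyad generation with known, tunable coordination structure.

Downstream modules are exercised on simulated conversations whose
coordination strength is controlled:

- movement: each participant's latent displacement is an
  Ornstein-Uhlenbeck (OU) process (Euler-Maruyama at the sampling
  rate); the devil's-advocate (DA) latent mixes an independent OU
  process with the naive partner's latent delayed by ``coupling_lag_s``
  at weight ``coupling_gain``, then both are passed through a softplus
  to mimic nonnegative displacement with smooth autocorrelation;
- speech: strictly alternating, non-overlapping turns with exponential
  durations; syllable onsets are a Poisson point process within each
  turn whose rate partially matches the partner's realized rate on the
  previous turn (weight ``matching_c``);
- video: a textured block per region of interest jiggles with an
  amplitude proportional to the participant's displacement series, so
  motion-energy extraction recovers the latent series.

Condition effects enter ONLY through (coupling_gain, coupling_lag_s,
matching_c) — coordination structure, not marginal levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (FrameStack, GeometryError, ParameterError, RegionSpec,
                   UniformSeries)

__all__ = ["MovementSimParams", "SpeechSimParams", "ConditionCell",
           "ConditionEffects", "SpeechPairResult",
           "generate_movement_pair", "generate_speech_pair", "render_frames"]


@dataclass(frozen=True)
class MovementSimParams:
    """Coupled-movement simulation settings.

    ``coupling_gain`` g in [0, 1] weights the naive partner's delayed
    latent in the DA's signal; ``coupling_lag_s`` k >= 0 is the delay
    (naive leads the DA by k seconds).  ``ou_theta`` (1/s) and
    ``ou_sigma`` set the OU mean reversion and noise scale.
    """

    duration_s: float = 480.0
    rate_hz: float = 6.0
    coupling_gain: float = 0.5
    coupling_lag_s: float = 0.5
    ou_theta: float = 0.8
    ou_sigma: float = 1.0
    nonneg_transform: Literal["softplus", "abs", "none"] = "softplus"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_gain <= 1.0):
            raise ParameterError("coupling_gain must be in [0, 1]")
        if self.coupling_lag_s < 0:
            raise ParameterError("coupling_lag_s must be >= 0")
        if self.duration_s * self.rate_hz < 2:
            raise ParameterError("duration_s * rate_hz must be >= 2")
        if self.ou_theta <= 0 or self.ou_sigma < 0:
            raise ParameterError("ou_theta must be > 0 and ou_sigma >= 0")
        if self.nonneg_transform not in ("softplus", "abs", "none"):
            raise ParameterError(
                f"unknown nonneg_transform {self.nonneg_transform!r}")


@dataclass(frozen=True)
class SpeechSimParams:
    """Alternating-turn speech simulation settings.

    Turn durations are exponential with mean ``turn_mean_s`` truncated
    at a 1-second minimum.  Each new turn's generating syllable rate is
    ``(1-c) * own base + c * partner's realized rate on the previous
    turn``, plus Gaussian noise (``rate_noise_sd``), clipped at zero.
    """

    duration_s: float = 480.0
    base_rate_a: float = 3.5
    base_rate_b: float = 4.5
    matching_c: float = 0.5
    turn_mean_s: float = 8.0
    rate_noise_sd: float = 0.4
    inter_turn_gap_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.matching_c <= 1.0):
            raise ParameterError("matching_c must be in [0, 1]")
        if self.base_rate_a <= 0 or self.base_rate_b <= 0:
            raise ParameterError("base rates must be > 0")
        if self.turn_mean_s <= 0 or self.duration_s <= 0:
            raise ParameterError("durations must be > 0")
        if self.rate_noise_sd < 0 or self.inter_turn_gap_s < 0:
            raise ParameterError("noise and gap must be >= 0")


@dataclass(frozen=True)
class ConditionCell:
    """Coordination parameters for one (veracity, conflict) cell."""

    coupling_gain: float
    coupling_lag_s: float
    matching_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_gain <= 1.0):
            raise ParameterError("coupling_gain must be in [0, 1]")
        if self.coupling_lag_s < 0:
            raise ParameterError("coupling_lag_s must be >= 0")
        if not (0.0 <= self.matching_c <= 1.0):
            raise ParameterError("matching_c must be in [0, 1]")


VERACITY_LEVELS = ("deception", "truth")
CONFLICT_LEVELS = ("disagree", "agree")


@dataclass(frozen=True)
class ConditionEffects:
    """Map (veracity, conflict) -> coordination parameters, all four cells.

    The default encodes the qualitative target pattern of the study
    design — coordination greatest in deceptive conversations involving
    disagreement — purely through coupling structure.
    """

    cells: dict[tuple[str, str], ConditionCell] = field(default_factory=lambda: {
        ("deception", "disagree"): ConditionCell(0.7, 0.5, 0.7),
        ("deception", "agree"): ConditionCell(0.5, 0.5, 0.5),
        ("truth", "disagree"): ConditionCell(0.4, 0.3, 0.4),
        ("truth", "agree"): ConditionCell(0.3, 0.3, 0.3),
    })

    def __post_init__(self) -> None:
        expected = {(v, c) for v in VERACITY_LEVELS for c in CONFLICT_LEVELS}
        if set(self.cells) != expected:
            raise ParameterError(
                f"condition cells must be exactly {sorted(expected)}")

    def __getitem__(self, key: tuple[str, str]) -> ConditionCell:
        return self.cells[key]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "softplus":
        return _softplus(x)
    if kind == "abs":
        return np.abs(x)
    return x.copy()


def _ou(n: int, theta: float, sigma: float, dt: float,
        rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama simulation of a zero-mean OU process, stationary start."""
    sd_stat = sigma / np.sqrt(2.0 * theta) if sigma > 0 else 0.0
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd_stat) if sd_stat > 0 else 0.0
    noise = rng.normal(0.0, sigma * np.sqrt(dt), size=n - 1)
    for i in range(1, n):
        x[i] = x[i - 1] - theta * x[i - 1] * dt + noise[i - 1]
    return x


def generate_movement_pair(
    params: MovementSimParams,
) -> tuple[UniformSeries, UniformSeries]:
    """Simulate a (naive, DA) pair of movement-displacement series.

    The DA latent is ``(1-g) * independent OU + g * naive latent delayed
    by round(k * rate) samples``; both latents pass through the
    nonnegativity transform.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    lag = int(round(params.coupling_lag_s * params.rate_hz))
    dt = 1.0 / params.rate_hz

    # simulate the naive latent with a `lag`-sample prefix so the delayed
    # copy aligns exactly: naive[t] = latent[t + lag], coupled term = latent[t]
    latent_n = _ou(n + lag, params.ou_theta, params.ou_sigma, dt, rng)
    latent_i = _ou(n, params.ou_theta, params.ou_sigma, dt, rng)
    g = params.coupling_gain
    naive_lat = latent_n[lag:lag + n]
    da_lat = (1.0 - g) * latent_i + g * latent_n[:n]

    naive = UniformSeries(_transform(naive_lat, params.nonneg_transform),
                          rate_hz=params.rate_hz)
    da = UniformSeries(_transform(da_lat, params.nonneg_transform),
                       rate_hz=params.rate_hz)
    return naive, da


@dataclass(frozen=True)
class SpeechPairResult:
    """Events and tiers for both speakers plus the per-turn bookkeeping.

    ``turns`` records (speaker, start_s, end_s, gen_rate, realized_rate)
    for each turn in order; ``gen_rate`` is the Poisson intensity used,
    ``realized_rate`` the realized onsets-per-second.
    """

    events_a: "EventTimes"
    tier_a: "UtteranceTier"
    events_b: "EventTimes"
    tier_b: "UtteranceTier"
    turns: list[tuple[str, float, float, float, float]]


def generate_speech_pair(params: SpeechSimParams) -> SpeechPairResult:
    """Simulate alternating-turn speech with partner rate matching."""
    from .speech import EventTimes, UtteranceTier  # avoid import cycle

    rng = np.random.default_rng(params.seed)
    speaker = "A" if rng.random() < 0.5 else "B"
    t = 0.0
    prev_realized: float | None = None
    intervals: dict[str, list[tuple[float, float]]] = {"A": [], "B": []}
    onsets: dict[str, list[float]] = {"A": [], "B": []}
    turns: list[tuple[str, float, float, float, float]] = []

    while True:
        dur = max(1.0, rng.exponential(params.turn_mean_s))
        if t + dur > params.duration_s:
            dur = params.duration_s - t
            if dur < 1.0:
                break
        base = params.base_rate_a if speaker == "A" else params.base_rate_b
        c = params.matching_c
        rate = base if prev_realized is None else (1 - c) * base + c * prev_realized
        if params.rate_noise_sd > 0:
            rate += rng.normal(0.0, params.rate_noise_sd)
        rate = max(rate, 0.0)

        count = rng.poisson(rate * dur)
        pts = np.sort(rng.uniform(t + 1e-6, t + dur - 1e-6, size=count))
        pts = np.unique(pts)
        intervals[speaker].append((t, t + dur))
        onsets[speaker].extend(pts.tolist())
        realized = len(pts) / dur
        turns.append((speaker, t, t + dur, rate, realized))
        prev_realized = realized

        t += dur + params.inter_turn_gap_s
        speaker = "B" if speaker == "A" else "A"
        if t >= params.duration_s - 1.0:
            break

    def tier(sp: str) -> UtteranceTier:
        return UtteranceTier(sp, np.asarray(intervals[sp], float).reshape(-1, 2))

    return SpeechPairResult(
        events_a=EventTimes("A", np.asarray(onsets["A"])),
        tier_a=tier("A"),
        events_b=EventTimes("B", np.asarray(onsets["B"])),
        tier_b=tier("B"),
        turns=turns,
    )


def render_frames(
    naive: UniformSeries,
    da: UniformSeries,
    rois: tuple[RegionSpec, RegionSpec],
    frame_shape: tuple[int, int] = (64, 96),
    fps: float = 30.0,
    max_shift_px: int = 8,
    px_per_unit: float | None = None,
    background: int = 128,
) -> FrameStack:
    """Render a frame stack whose ROI pixel change tracks the two series.

    Inside each region of interest a horizontally gradient-textured
    block jiggles left/right on alternating frames with an offset
    proportional to that participant's series value (held over the
    ``fps / rate_hz`` frames of each sample), so frame differencing at
    matching step recovers the series.  ``px_per_unit`` defaults to
    mapping the larger series maximum to ``max_shift_px``.
    """
    h, w = frame_shape
    ratio = fps / naive.rate_hz
    if abs(ratio - round(ratio)) > 1e-9 or naive.rate_hz != da.rate_hz:
        raise ParameterError("fps must be an integer multiple of the series rate")
    for roi in rois:
        roi.validate_for(h, w)
        if roi.width <= 2 * max_shift_px + 2 or roi.height <= 2:
            raise GeometryError(f"ROI {roi.label} too small for shift "
                                f"{max_shift_px}px")
    n = min(len(naive), len(da))
    upsample = int(round(ratio))
    n_frames = n * upsample
    vmax = max(float(np.max(naive.values[:n])), float(np.max(da.values[:n])), 1e-12)
    gain = (max_shift_px / vmax) if px_per_unit is None else px_per_unit

    base = np.full((h, w, 3), background, dtype=np.uint8)
    frames = np.repeat(base[None], n_frames, axis=0)
    series = (naive, da)
    for roi, s in zip(rois, series):
        bw = roi.width - 2 * max_shift_px
        bh = roi.height
        # horizontal gradient; slope chosen so a 1-px shift changes each
        # block pixel by a fixed amount without wrapping
        slope = max(1, min(6, 200 // max(bw, 1)))
        col = (20 + slope * np.arange(bw + 2 * max_shift_px)).clip(0, 255)
        block = np.broadcast_to(col[None, :bw, None], (bh, bw, 3)).astype(np.uint8)
        vals = s.values[:n]
        offs = np.rint(gain * np.repeat(vals, upsample)).astype(int)
        offs = np.clip(offs, 0, max_shift_px)
        sign = np.where(np.arange(n_frames) % 2 == 0, 1, -1)
        offs = offs * sign
        y0, x0 = roi.y0, roi.x0 + max_shift_px
        for f in range(n_frames):
            x = x0 + offs[f]
            frames[f, y0:y0 + bh, x:x + bw, :] = block
    return FrameStack(frames, fps=fps)
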