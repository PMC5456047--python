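"""Windowed lagged cross-correlation (WLCC) between two movement series.

Pearson correlations are computed inside short tumbling windows (10 s by
default), repeated over relative lags on the sample grid (1/6 s steps up
to +/- 5 s), and aggregated across windows into a lag profile.  The sign
convention: at positive lag the DA's samples are paired with the naive
partner's EARLIER samples, so a profile peak at positive lag means the
DA follows the naive participant.

Three aggregate indices summarize the profile: ``lag0`` (mean r over lag
0 and one sample either side — near-simultaneous movement), and
``da_follows_1000`` / ``naive_follows_1000`` (mean r over the remaining
positive / negative lags out to 1000 ms — immediate responsiveness of
one partner to the other).  Coarser 1000-ms lag-bin means (out to
+/- 3000 ms) feed the prediction stage.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (CoverageError, InputError, ParameterError,
                   RateMismatchError, UniformSeries)

__all__ = ["WlccParams", "LagProfile", "WlccSummary",
           "lag_profile", "summarize", "lag_bin_features"]


@dataclass(frozen=True)
class WlccParams:
    """Windowing, lag grid and aggregation settings.

    ``lag_step_s`` must equal one sample period of the input series and
    ``max_lag_s`` must be a multiple of it.  ``min_window_fraction`` is
    the fraction of a window that must have valid sample pairs at a
    given lag for that window to contribute.
    """

    window_s: float = 10.0
    window_step_s: float = 10.0
    max_lag_s: float = 5.0
    lag_step_s: float = 1.0 / 6.0
    min_window_fraction: float = 0.8
    aggregate: Literal["mean", "fisher_z_mean"] = "mean"

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.window_step_s <= 0:
            raise ParameterError("window_s and window_step_s must be > 0")
        if self.lag_step_s <= 0 or self.max_lag_s < 0:
            raise ParameterError("invalid lag grid")
        ratio = self.max_lag_s / self.lag_step_s
        if abs(ratio - round(ratio)) > 1e-6:
            raise ParameterError("max_lag_s must be a multiple of lag_step_s")
        if not (0 < self.min_window_fraction <= 1):
            raise ParameterError("min_window_fraction must be in (0, 1]")
        if self.aggregate not in ("mean", "fisher_z_mean"):
            raise ParameterError(f"unknown aggregate {self.aggregate!r}")


@dataclass(frozen=True)
class LagProfile:
    """Per-window, per-lag correlations and their aggregate.

    ``r_by_window`` is (n_windows, n_lags) with NaN marking windows that
    were dropped at a lag (insufficient overlap or zero variance);
    ``r_mean`` aggregates the valid windows per lag.
    """

    lags_s: np.ndarray
    r_by_window: np.ndarray
    r_mean: np.ndarray
    rate_hz: float

    @property
    def n_windows(self) -> int:
        return self.r_by_window.shape[0]

    def argmax_lag_s(self) -> float:
        """Lag (s) at which the aggregated profile peaks."""
        return float(self.lags_s[np.nanargmax(self.r_mean)])


@dataclass(frozen=True)
class WlccSummary:
    """The three aggregate movement-coordination indices (NaN = missing)."""

    lag0: float
    da_follows_1000: float
    naive_follows_1000: float


def _align(da: UniformSeries, naive: UniformSeries) -> tuple[np.ndarray, np.ndarray, float]:
    if abs(da.rate_hz - naive.rate_hz) > 1e-9 * max(da.rate_hz, naive.rate_hz):
        raise RateMismatchError(
            f"sampling rates differ: {da.rate_hz} vs {naive.rate_hz}")
    if abs(da.t0 - naive.t0) > 0.5 / da.rate_hz:
        raise InputError("series start times differ by more than half a sample")
    n = min(len(da), len(naive))
    return da.values[:n], naive.values[:n], da.rate_hz


def lag_profile(da: UniformSeries, naive: UniformSeries,
                params: WlccParams = WlccParams()) -> LagProfile:
    """Windowed lagged cross-correlation of ``da`` against ``naive``.

    For window w starting at sample s (length W) and lag ``l`` in
    samples, ``r_w(l)`` is the Pearson correlation of ``da[t]`` with
    ``naive[t - l]`` over the window, using only index pairs where the
    lagged sample exists (lagged samples are drawn from beyond the
    window edge when available).  Windows with fewer than
    ``min_window_fraction * W`` valid pairs, or zero variance in either
    slice, contribute NaN.
    """
    x, y, rate = _align(da, naive)
    if abs(params.lag_step_s * rate - 1.0) > 1e-6:
        raise ParameterError(
            f"lag_step_s={params.lag_step_s} is not one sample period "
            f"at {rate} Hz")
    n = len(x)
    w_len = int(round(params.window_s * rate))
    if n < w_len:
        raise InputError(
            f"overlapping span ({n} samples) shorter than one window ({w_len})")
    step = max(1, int(round(params.window_step_s * rate)))
    max_lag = int(round(params.max_lag_s * rate))
    lags = np.arange(-max_lag, max_lag + 1)

    # pad the naive series so every lagged window slice has length w_len
    pad = np.full(max_lag, np.nan)
    y_pad = np.concatenate([pad, y, pad])
    slices = np.lib.stride_tricks.sliding_window_view(y_pad, w_len)

    starts = np.arange(0, n - w_len + 1, step)
    min_pairs = int(np.ceil(params.min_window_fraction * w_len))
    r_by_window = np.full((len(starts), len(lags)), np.nan)

    for wi, s in enumerate(starts):
        xw = x[s:s + w_len]
        # row per lag: naive[s-l : s-l+w_len] lives at padded offset s+max_lag-l
        yw = slices[s + max_lag - lags]  # (n_lags, w_len)
        valid = np.isfinite(yw)
        n_valid = valid.sum(axis=1)
        ok = n_valid >= min_pairs

        xm = np.where(valid, xw[None, :], 0.0)
        ym = np.where(valid, yw, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            nv = np.maximum(n_valid, 1)
            mx = xm.sum(axis=1) / nv
            my = ym.sum(axis=1) / nv
            dx = np.where(valid, xw[None, :] - mx[:, None], 0.0)
            dy = np.where(valid, yw - my[:, None], 0.0)
            sxx = (dx * dx).sum(axis=1)
            syy = (dy * dy).sum(axis=1)
            sxy = (dx * dy).sum(axis=1)
            r = sxy / np.sqrt(sxx * syy)
        r[~ok | (sxx <= 0) | (syy <= 0)] = np.nan
        r_by_window[wi] = np.clip(r, -1.0, 1.0)

    r_mean = _aggregate(r_by_window, params.aggregate)
    return LagProfile(lags_s=lags / rate, r_by_window=r_by_window,
                      r_mean=r_mean, rate_hz=rate)


def _aggregate(r_by_window: np.ndarray, how: str) -> np.ndarray:
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if how == "fisher_z_mean":
            z = np.arctanh(np.clip(r_by_window, -1 + 1e-15, 1 - 1e-15))
            return np.tanh(np.nanmean(z, axis=0))
        return np.nanmean(r_by_window, axis=0)


def _lag_samples(profile: LagProfile) -> np.ndarray:
    return np.round(profile.lags_s * profile.rate_hz).astype(int)


def summarize(profile: LagProfile) -> WlccSummary:
    """Aggregate a lag profile into the three coordination indices.

    ``lag0`` averages lags {-1, 0, +1} samples; ``da_follows_1000`` the
    positive lags beyond one sample out to 1000 ms (5 lags at 6 Hz);
    ``naive_follows_1000`` the mirror negative lags.  A missing lag mean
    (all windows dropped) propagates to NaN in the summary.
    """
    ell = _lag_samples(profile)
    max_1s = int(round(profile.rate_hz))  # samples within 1000 ms
    if ell.min() > -max_1s or ell.max() < max_1s:
        raise CoverageError("profile must cover lags out to +/-1000 ms")

    def band(mask: np.ndarray) -> float:
        return float(np.mean(profile.r_mean[mask]))  # NaN propagates

    return WlccSummary(
        lag0=band(np.abs(ell) <= 1),
        da_follows_1000=band((ell >= 2) & (ell <= max_1s)),
        naive_follows_1000=band((ell <= -2) & (ell >= -max_1s)),
    )


def lag_bin_features(profile: LagProfile, n_bins: int = 3) -> dict[int, float]:
    """Coarse 1000-ms lag-bin means of the aggregated profile.

    Bin 0 covers lags {-1, 0, +1} samples; bin +b (b >= 1) covers
    positive lags in ((b-1) s, b s] excluding bin 0's samples, and bin
    -b the mirror.  These seven bins (b up to 3) are the movement
    features entering prediction, one set per body region.
    """
    ell = _lag_samples(profile)
    rate = int(round(profile.rate_hz))
    out: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out[0] = float(np.mean(profile.r_mean[np.abs(ell) <= 1]))
        for b in range(1, n_bins + 1):
            lo = max(2, (b - 1) * rate + 1)
            hi = b * rate
            if hi > ell.max():
                raise CoverageError(f"profile does not cover bin +/-{b}")
            pos = (ell >= lo) & (ell <= hi)
            neg = (ell <= -lo) & (ell >= -hi)
            out[b] = float(np.mean(profile.r_mean[pos]))
            out[-b] = float(np.mean(profile.r_mean[neg]))
    return out
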