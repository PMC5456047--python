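"""Cross-recurrence quantification analysis (CRQA) of two time series.

Each series is (optionally z-scored and) delay-embedded into
``m``-dimensional states; the cross-recurrence plot marks every pair of
times (i, j) at which speaker A's state i and speaker B's state j lie
within radius ``eps`` of each other.  Six indices quantify the plot:

- RR    recurrence rate: fraction of recurrent (i, j) pairs — how often
        the two speakers visit similar speech-rate states at any lag;
- DET   fraction of recurrent points that fall on diagonal lines of
        length >= lmin — recurrences forming repeated sequences rather
        than isolated matches;
- L     mean diagonal line length — typical duration of a shared
        sequence;
- LMAX  longest diagonal line;
- T2    recurrence time of the second type: mean gap between the START
        indices of consecutive vertical recurrence runs within a
        column — average spacing between revisits;
- ENTR  Shannon entropy (nats) of the diagonal line-length histogram —
        diversity of shared-sequence durations.

Undefined indices (e.g. L on a plot with no diagonal line, T2 with no
column revisit) are reported as NaN, never as zero.  The main diagonal
is not excluded: a cross-recurrence plot between distinct series has no
trivial line of identity (self-comparisons therefore show LMAX equal to
the embedded length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import (CalibrationError, InputError, NormalizationError,
                   ParameterError, UniformSeries)

__all__ = ["EmbeddingParams", "RecurrencePlot", "RecurrenceMetrics",
           "embed", "cross_recurrence", "quantify", "crqa_metrics",
           "calibrate_radius"]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding, thresholding and line-counting settings.

    ``radius`` is expressed in z-score units when ``normalize='zscore'``
    (the default).  ``theiler`` excludes a band |i - j| < theiler around
    the main diagonal from recurrence counting (default 0: no
    exclusion).
    """

    m: int = 3
    tau: int = 3
    radius: float = 0.5
    norm: Literal["euclidean", "maximum"] = "euclidean"
    normalize: Literal["zscore", "none"] = "zscore"
    lmin: int = 2
    theiler: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ParameterError("embedding needs m >= 1 and tau >= 1")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")
        if self.lmin < 2:
            raise ParameterError("lmin must be >= 2")
        if self.theiler < 0:
            raise ParameterError("theiler must be >= 0")
        if self.norm not in ("euclidean", "maximum"):
            raise ParameterError(f"unknown norm {self.norm!r}")
        if self.normalize not in ("zscore", "none"):
            raise ParameterError(f"unknown normalize {self.normalize!r}")


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary cross-recurrence matrix: rows = A's states, cols = B's."""

    matrix: np.ndarray
    params: EmbeddingParams | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise InputError("recurrence matrix must be 2-D and nonempty")
        object.__setattr__(self, "matrix", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass(frozen=True)
class RecurrenceMetrics:
    """The six CRQA indices; NaN marks an undefined value."""

    rr: float
    det: float
    l_mean: float
    lmax: int
    t2: float
    entr: float

    def as_dict(self) -> dict[str, float]:
        return {"RR": self.rr, "DET": self.det, "L": self.l_mean,
                "LMAX": float(self.lmax), "T2": self.t2, "ENTR": self.entr}


def embed(values: np.ndarray | UniformSeries, m: int, tau: int) -> np.ndarray:
    """Takens delay embedding: state i = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    x = values.values if isinstance(values, UniformSeries) else np.asarray(values, float)
    n_emb = len(x) - (m - 1) * tau
    if n_emb < 2:
        raise InputError(
            f"embedded length {n_emb} < 2 (n={len(x)}, m={m}, tau={tau})")
    return np.column_stack([x[k * tau: k * tau + n_emb] for k in range(m)])


def _zscore(x: np.ndarray, label: str) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise NormalizationError(f"zero-variance series ({label}) cannot be z-scored")
    return (x - np.mean(x)) / sd


def _distances(a: UniformSeries | np.ndarray, b: UniformSeries | np.ndarray,
               p: EmbeddingParams) -> np.ndarray:
    xa = a.values if isinstance(a, UniformSeries) else np.asarray(a, float)
    xb = b.values if isinstance(b, UniformSeries) else np.asarray(b, float)
    if p.normalize == "zscore":
        xa, xb = _zscore(xa, "A"), _zscore(xb, "B")
    ea, eb = embed(xa, p.m, p.tau), embed(xb, p.m, p.tau)
    metric = "euclidean" if p.norm == "euclidean" else "chebyshev"
    return cdist(ea, eb, metric=metric)


def cross_recurrence(a: UniformSeries | np.ndarray, b: UniformSeries | np.ndarray,
                     p: EmbeddingParams = EmbeddingParams()) -> RecurrencePlot:
    """Threshold the cross-distance matrix of the embedded series at ``radius``."""
    d = _distances(a, b, p)
    mat = d <= p.radius
    if p.theiler > 0:
        n1, n2 = mat.shape
        i = np.arange(n1)[:, None]
        j = np.arange(n2)[None, :]
        mat = mat & (np.abs(i - j) >= p.theiler)
    return RecurrencePlot(mat, params=p)


def _runs(line: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if not line.any():
        return []
    padded = np.concatenate([[False], line, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return (edges[1::2] - edges[0::2]).tolist()


def _run_starts(line: np.ndarray) -> np.ndarray:
    padded = np.concatenate([[False], line])
    return np.flatnonzero(~padded[:-1] & line)


def quantify(rp: RecurrencePlot, lmin: int = 2) -> RecurrenceMetrics:
    """Compute the six CRQA indices from a binary recurrence plot.

    Diagonal lines are maximal runs of recurrent points along the
    (i+1, j+1) direction on every diagonal of the matrix; lines shorter
    than ``lmin`` are ignored for DET, L, LMAX and ENTR.  An all-zero
    plot yields RR=0, LMAX=0, and NaN for the remaining indices.
    """
    mat = rp.matrix
    n1, n2 = mat.shape
    total = int(mat.sum())
    rr = total / (n1 * n2)

    lines: list[int] = []
    for k in range(-(n1 - 1), n2):
        for run in _runs(np.diagonal(mat, offset=k)):
            if run >= lmin:
                lines.append(run)

    if total == 0:
        det = np.nan
    else:
        det = sum(lines) / total
    if lines:
        l_mean = float(np.mean(lines))
        lmax = int(max(lines))
        counts = np.bincount(lines)[lmin:]
        p = counts[counts > 0] / len(lines)
        entr = float(-np.sum(p * np.log(p)))
    else:
        l_mean, lmax, entr = np.nan, 0, np.nan

    gaps: list[int] = []
    for j in range(n2):
        starts = _run_starts(mat[:, j])
        if len(starts) >= 2:
            gaps.extend(np.diff(starts).tolist())
    t2 = float(np.mean(gaps)) if gaps else np.nan

    return RecurrenceMetrics(rr=rr, det=det, l_mean=l_mean, lmax=lmax,
                             t2=t2, entr=entr)


def crqa_metrics(a: UniformSeries, b: UniformSeries,
                 p: EmbeddingParams = EmbeddingParams()) -> RecurrenceMetrics:
    """Convenience: embed, threshold and quantify in one call."""
    return quantify(cross_recurrence(a, b, p), lmin=p.lmin)


def calibrate_radius(
    pairs: Sequence[tuple[UniformSeries, UniformSeries]],
    p: EmbeddingParams = EmbeddingParams(),
    target_rr: float = 0.05,
    rel_tol: float = 0.10,
    max_iter: int = 100,
) -> float:
    """Find one global radius giving a pooled mean RR near ``target_rr``.

    Bisects on the radius until the mean recurrence rate across all
    pairs is within ``rel_tol`` (relative) of the target.  The resulting
    single global radius preserves between-condition RR differences,
    which a per-pair fixed-RR radius would erase.
    """
    if not pairs:
        raise InputError("calibration dataset is empty")
    if not (0 < target_rr <= 1):
        raise ParameterError("target_rr must be in (0, 1]")
    dists = [_distances(a, b, p) for a, b in pairs]

    def mean_rr(eps: float) -> float:
        return float(np.mean([np.mean(d <= eps) for d in dists]))

    lo, hi = 0.0, max(float(d.max()) for d in dists)
    if mean_rr(lo) > target_rr * (1 + rel_tol):
        raise CalibrationError(
            f"target RR {target_rr} unattainable: RR at radius 0 is "
            f"{mean_rr(lo):.4f} (tied/duplicate states)")
    if target_rr >= 1.0:
        return hi
    eps = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rr = mean_rr(mid)
        if abs(rr - target_rr) <= rel_tol * target_rr:
            return mid
        if rr < target_rr:
            lo = mid
        else:
            hi = mid
        eps = mid
    rr = mean_rr(eps)
    if abs(rr - target_rr) <= rel_tol * target_rr:
        return eps
    raise CalibrationError(
        f"bisection did not reach target RR {target_rr} "
        f"(last radius {eps:.6g}, RR {rr:.4f}); the RR step function may "
        f"jump across the target for these data")
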