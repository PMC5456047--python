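"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain loops and textbook
formulas — and stays independent of the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    sxx = ((x - mx) ** 2).sum()
    syy = ((y - my) ** 2).sum()
    if sxx == 0 or syy == 0:
        return math.nan
    return float(((x - mx) * (y - my)).sum() / math.sqrt(sxx * syy))


def wlcc_oracle(x, y, window, step, max_lag, min_fraction):
    """Per-window, per-lag correlations of x[t] with y[t-lag], by loops."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = min(len(x), len(y))
    starts = list(range(0, n - window + 1, step))
    lags = list(range(-max_lag, max_lag + 1))
    min_pairs = math.ceil(min_fraction * window)
    out = np.full((len(starts), len(lags)), np.nan)
    for wi, s in enumerate(starts):
        for li, lag in enumerate(lags):
            xs, ys = [], []
            for t in range(s, s + window):
                u = t - lag
                if 0 <= u < n:
                    xs.append(x[t])
                    ys.append(y[u])
            if len(xs) < min_pairs:
                continue
            out[wi, li] = pearson(xs, ys)
    return out


def motion_oracle(frames, roi, step, mode, threshold):
    """Triple-loop frame differencing inside an ROI."""
    n = frames.shape[0]
    values = []
    i = step
    while i < n:
        prev, cur = frames[i - step], frames[i]
        if mode == "sum_abs":
            total = 0
            for yy in range(roi.y0, roi.y1):
                for xx in range(roi.x0, roi.x1):
                    for ch in range(3):
                        total += abs(int(cur[yy, xx, ch]) - int(prev[yy, xx, ch]))
            values.append(float(total))
        else:
            count = 0
            for yy in range(roi.y0, roi.y1):
                for xx in range(roi.x0, roi.x1):
                    mx = max(abs(int(cur[yy, xx, ch]) - int(prev[yy, xx, ch]))
                             for ch in range(3))
                    if mx > threshold:
                        count += 1
            values.append(float(count))
        i += step
    return np.asarray(values)


def crqa_oracle(mat, lmin=2):
    """Exhaustive line enumeration of a binary recurrence matrix.

    Returns a dict with RR, DET, L, LMAX, T2, ENTR (NaN = undefined).
    """
    mat = np.asarray(mat, bool)
    n1, n2 = mat.shape
    total = int(mat.sum())
    rr = total / (n1 * n2)

    lines = []
    for k in range(-(n1 - 1), n2):
        run = 0
        for i in range(n1):
            j = i + k
            if 0 <= j < n2 and mat[i, j]:
                run += 1
            else:
                if run >= lmin:
                    lines.append(run)
                run = 0
        if run >= lmin:
            lines.append(run)

    det = (sum(lines) / total) if total > 0 else math.nan
    if lines:
        l_mean = float(np.mean(lines))
        lmax = max(lines)
        uniq, counts = np.unique(lines, return_counts=True)
        p = counts / len(lines)
        entr = float(-(p * np.log(p)).sum())
    else:
        l_mean, lmax, entr = math.nan, 0, math.nan

    gaps = []
    for j in range(n2):
        starts = [i for i in range(n1)
                  if mat[i, j] and (i == 0 or not mat[i - 1, j])]
        for a, b in zip(starts, starts[1:]):
            gaps.append(b - a)
    t2 = float(np.mean(gaps)) if gaps else math.nan
    return {"RR": rr, "DET": det, "L": l_mean, "LMAX": float(lmax),
            "T2": t2, "ENTR": entr}


def ba_posterior_convolution(tp, fn, tn, fp, grid=20001):
    """Mean and 95% quantiles of (X+Y)/2, X,Y independent Betas.

    Computed by numerical convolution of the two Beta densities on a
    fine grid.
    """
    a1, b1 = tp + 1, fn + 1
    a2, b2 = tn + 1, fp + 1
    x = np.linspace(0.0, 1.0, grid)
    dx = x[1] - x[0]
    f1 = stats.beta.pdf(x, a1, b1)
    f2 = stats.beta.pdf(x, a2, b2)
    conv = np.convolve(f1, f2) * dx          # density of X+Y on [0, 2]
    s = np.linspace(0.0, 2.0, 2 * grid - 1)
    conv /= np.trapezoid(conv, s)
    cdf = np.cumsum(conv) * dx
    cdf /= cdf[-1]
    mean_ba = 0.5 * (a1 / (a1 + b1) + a2 / (a2 + b2))
    q_lo = s[np.searchsorted(cdf, 0.025)] / 2.0
    q_hi = s[np.searchsorted(cdf, 0.975)] / 2.0
    return mean_ba, float(q_lo), float(q_hi)


def derangements(n):
    """All permutations of range(n) with no fixed point (for small n)."""
    from itertools import permutations
    return [p for p in permutations(range(n)) if all(p[i] != i for i in range(n))]
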