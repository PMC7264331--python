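"""Time-domain HRV markers (markers 1-11).

Conventions: RR in seconds throughout; per-series standard deviations use
the sample (ddof=1) estimator, the usual choice for SDNN/STDHR; the RR
histogram behind the triangular index and TINN uses the conventional
1/128 s (7.8125 ms) bin width.
"""

from __future__ import annotations

import numpy as np

from ..rr import RRSeries

HIST_BIN = 1.0 / 128.0  # s, conventional RR histogram resolution
NN50_THRESHOLD = 0.050  # s
WINDOW_5MIN = 300.0  # s


def _rr_histogram(rr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RR histogram on the fixed 1/128 s grid aligned at zero."""
    lo = np.floor(rr.min() / HIST_BIN)
    hi = np.floor(rr.max() / HIST_BIN) + 1
    edges = np.arange(lo, hi + 1) * HIST_BIN
    counts, _ = np.histogram(rr, bins=edges)
    return counts, edges


def triangular_index(rr: np.ndarray) -> float:
    """HRV triangular index: total beat count over the histogram mode height."""
    counts, _ = _rr_histogram(rr)
    return float(rr.size / counts.max())


def tinn(rr: np.ndarray) -> float:
    """Baseline width of the least-squares triangular fit to the RR histogram.

    The triangle rises from zero at N to the histogram peak (X, Y) and falls
    back to zero at M; N and M are optimised independently (the squared error
    splits at the peak) over the histogram bin centres, and TINN = M - N.
    """
    counts, edges = _rr_histogram(rr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(counts))
    x, y = centers[k], float(counts[k])

    def best_side(idx: np.ndarray, left: bool) -> float:
        # candidate apex positions for the zero end of the triangle
        if idx.size == 0:
            return x
        best_err, best_pos = np.inf, centers[idx[0]] if left else centers[idx[-1]]
        candidates = centers[idx[0]] - HIST_BIN, centers[idx[-1]] + HIST_BIN
        # evaluate every bin centre (plus one bin beyond) as the triangle foot
        feet = np.concatenate((centers[idx], [candidates[0] if left else candidates[1]]))
        for foot in feet:
            if left:
                ramp = np.where(
                    (centers[idx] >= foot), y * (centers[idx] - foot) / (x - foot), 0.0
                ) if x != foot else np.full(idx.size, y)
                ramp = np.where(centers[idx] < foot, 0.0, ramp)
            else:
                ramp = np.where(
                    (centers[idx] <= foot), y * (foot - centers[idx]) / (foot - x), 0.0
                ) if x != foot else np.full(idx.size, y)
                ramp = np.where(centers[idx] > foot, 0.0, ramp)
            err = float(np.sum((counts[idx] - ramp) ** 2))
            if err < best_err:
                best_err, best_pos = err, foot
        return float(best_pos)

    n_pos = best_side(np.arange(0, k), left=True)
    m_pos = best_side(np.arange(k + 1, centers.size), left=False)
    return float(m_pos - n_pos)


def five_minute_stats(series: RRSeries) -> tuple[float, float]:
    """(mean of per-5-min SDs, SD of per-5-min means) over complete windows.

    Known as the SDNN index and SDANN.  Windows are consecutive 300 s spans
    anchored at the first beat; the trailing partial window is discarded.
    Requires at least two complete windows (total duration >= 10 min).
    """
    ends = series.beat_times[1:]
    n_win = int(ends[-1] // WINDOW_5MIN)
    if n_win < 2:
        raise ValueError("need at least 10 minutes of data for 5-min statistics")
    idx = np.ceil(ends / WINDOW_5MIN).astype(int) - 1
    rr = series.intervals
    sds, means = [], []
    for w in range(n_win):
        chunk = rr[idx == w]
        if chunk.size >= 2:
            sds.append(np.std(chunk, ddof=1))
            means.append(chunk.mean())
    return float(np.mean(sds)), float(np.std(means, ddof=1))


def time_domain_markers(series: RRSeries) -> dict[int, float]:
    """Markers 1-11 keyed by marker index.

    Markers 10-11 (5-minute statistics) require >= 10 min of data and are
    reported as NaN (absent) on shorter series.
    """
    rr = series.intervals
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    diffs = np.diff(rr)
    hr = 60.0 / rr
    nn50 = int(np.count_nonzero(np.abs(diffs) > NN50_THRESHOLD))
    out = {
        1: float(rr.mean()),
        2: float(np.std(rr, ddof=1)),
        3: float(hr.mean()),
        4: float(np.std(hr, ddof=1)),
        5: float(np.sqrt(np.mean(diffs**2))),
        6: float(nn50),
        7: 100.0 * nn50 / diffs.size,
        8: triangular_index(rr),
        9: tinn(rr),
    }
    try:
        sdnn_index, sdann = five_minute_stats(series)
    except ValueError:
        sdnn_index = sdann = float("nan")
    out[10] = sdnn_index
    out[11] = sdann
    return out
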