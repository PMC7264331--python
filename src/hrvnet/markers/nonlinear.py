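"""Non-linear HRV markers (markers 38-49).

Poincaré dispersions, recurrence quantification (REC/DET/line-length
statistics and their Shannon entropy), approximate and sample entropy,
detrended fluctuation analysis exponents, and the Grassberger-Procaccia
correlation dimension.  Default parameters follow common HRV-tool practice:
RQA with embedding m=10, delay 1, radius sqrt(m) x SD, minimum line length 2;
ApEn/SampEn with m=2, r = 0.2 x SDNN; DFA short range 4-16 beats and long
range 16-64 beats.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..rr import RRSeries


def poincare_markers(series: RRSeries) -> dict[int, float]:
    """Markers 38-39: SD1/SD2 of the lag-1 return map.

    SD1 is the RMS dispersion orthogonal to the identity line (algebraically
    RMSSD/sqrt(2)); SD2 the RMS dispersion along it, about the series mean.
    """
    rr = series.intervals
    if rr.size < 3:
        raise ValueError("need at least 3 intervals for the Poincare plot")
    d = np.diff(rr)
    sd1 = float(np.sqrt(np.mean(d**2) / 2.0))
    s = rr[1:] + rr[:-1] - 2.0 * rr.mean()
    sd2 = float(np.sqrt(np.mean(s**2) / 2.0))
    return {38: sd1, 39: sd2}


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short for embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _diagonal_lines(rec: np.ndarray, l_min: int) -> np.ndarray:
    """Lengths (>= l_min) of runs of recurrences on the upper off-diagonals."""
    n = rec.shape[0]
    lengths: list[int] = []
    for off in range(1, n):
        diag = np.diagonal(rec, offset=off)
        if not diag.any():
            continue
        padded = np.concatenate(([0], diag.astype(np.int8), [0]))
        d = np.diff(padded)
        runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        lengths.extend(runs[runs >= l_min].tolist())
    return np.asarray(lengths, dtype=int)


def recurrence_markers(
    series: RRSeries,
    m: int = 10,
    tau: int = 1,
    r_factor: float | None = None,
    l_min: int = 2,
) -> dict[int, float]:
    """Markers 40-44 from the recurrence plot of the embedded series.

    The recurrence matrix is R_ij = 1 iff the Euclidean distance between
    m-dimensional delay vectors is <= r, with r = r_factor x SD of the
    series (r_factor defaults to sqrt(m)).  REC is the percentage of
    recurrence points off the main diagonal; DET the percentage of those
    lying on diagonal lines of length >= l_min; markers 40/41 are the mean
    and maximum diagonal line length and 44 the Shannon entropy (nats) of
    the line-length distribution.
    """
    rr = series.intervals
    if rr.size <= m * tau + l_min:
        raise ValueError("series too short for recurrence analysis")
    if r_factor is None:
        r_factor = float(np.sqrt(m))
    r = r_factor * np.std(rr, ddof=1)
    emb = _embed(rr, m, tau)
    dist = squareform(pdist(emb))
    rec = dist <= r
    n = rec.shape[0]
    n_points = int(rec.sum()) - n  # exclude the main diagonal
    rec_rate = 100.0 * n_points / (n * n - n)
    lengths = _diagonal_lines(rec, l_min)
    if lengths.size == 0:
        det = 0.0
        rpl_mean = rpl_max = shan_en = float("nan")
    else:
        det = 100.0 * 2.0 * lengths.sum() / n_points if n_points else 0.0
        rpl_mean = float(lengths.mean())
        rpl_max = float(lengths.max())
        _, counts = np.unique(lengths, return_counts=True)
        p = counts / counts.sum()
        shan_en = float(-(p * np.log(p)).sum())
    return {40: rpl_mean, 41: rpl_max, 42: rec_rate, 43: min(det, 100.0), 44: shan_en}


def _template_match_matrices(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev template-match indicator matrices at lengths m and m+1."""
    n = x.size
    d1 = np.abs(x[:, None] - x[None, :]) <= r
    cm = d1[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        cm &= d1[k : n - m + 1 + k, k : n - m + 1 + k]
    cm1 = cm[: n - m, : n - m] & d1[m:, m:]
    return cm, cm1


def approximate_entropy(series: RRSeries, m: int = 2, r_factor: float = 0.2) -> float:
    """ApEn(m, r = r_factor x SDNN); self-matches included."""
    rr = series.intervals
    if rr.size < 50:
        raise ValueError("need at least 50 intervals for ApEn")
    r = r_factor * np.std(rr, ddof=1)
    n = rr.size
    cm, cm1 = _template_match_matrices(rr, m, r)
    phi_m = np.mean(np.log(cm.sum(axis=1) / (n - m + 1)))
    phi_m1 = np.mean(np.log(cm1.sum(axis=1) / (n - m)))
    return float(phi_m - phi_m1)


def sample_entropy(series: RRSeries, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r = r_factor x SDNN); self-matches excluded.

    Returns NaN with a warning when no template pair matches at length m+1.
    """
    rr = series.intervals
    if rr.size < 50:
        raise ValueError("need at least 50 intervals for SampEn")
    r = r_factor * np.std(rr, ddof=1)
    n = rr.size
    cm, cm1 = _template_match_matrices(rr, m, r)
    # restrict both lengths to the common N-m templates; remove self-matches
    b = float(cm[: n - m, : n - m].sum() - (n - m))
    a = float(cm1.sum() - (n - m))
    if a <= 0 or b <= 0:
        warnings.warn("no template matches; SampEn undefined", stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


def dfa_alphas(
    series: RRSeries,
    short_range: tuple[int, int] = (4, 16),
    long_range: tuple[int, int] = (16, 64),
) -> dict[int, float]:
    """Markers 47-48: DFA scaling exponents alpha1 (short) and alpha2 (long).

    The mean-centred series is integrated; per window of n beats a linear
    trend is removed and the RMS fluctuation F(n) computed; each alpha is
    the slope of log F(n) vs log n over its window range.
    """
    rr = series.intervals
    if rr.size < 256:
        raise ValueError("need at least 256 intervals for DFA")
    y = np.cumsum(rr - rr.mean())
    if np.allclose(y, 0.0):
        return {47: float("nan"), 48: float("nan")}

    def fluct(n: int) -> float:
        k = y.size // n
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n)
        t_c = t - t.mean()
        denom = (t_c**2).sum()
        slope = seg @ t_c / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t_c[None, :]
        return float(np.sqrt(np.mean(resid**2)))

    def alpha(lo: int, hi: int) -> float:
        sizes = np.unique(np.geomspace(lo, hi, 10).round().astype(int))
        f = np.array([fluct(n) for n in sizes])
        good = f > 0
        if good.sum() < 2:
            return float("nan")
        return float(np.polyfit(np.log(sizes[good]), np.log(f[good]), 1)[0])

    return {47: alpha(*short_range), 48: alpha(*long_range)}


def correlation_dimension(
    series: RRSeries,
    m: int = 10,
    tau: int = 1,
    percentile_range: tuple[float, float] = (2.0, 25.0),
) -> float:
    """Marker 49: Grassberger-Procaccia correlation dimension D2.

    The correlation integral C(r) of the m-embedded series is evaluated on a
    log-spaced radius grid spanning the stated inter-point-distance
    percentile range (the scaling region used for the log-log slope).
    Degenerate (zero-variance) series give NaN.
    """
    rr = series.intervals
    if rr.size < 500:
        raise ValueError("need at least 500 intervals for D2")
    if np.std(rr) == 0:
        return float("nan")
    emb = _embed(rr, m, tau)
    d = pdist(emb)
    d = d[d > 0]
    if d.size < 10:
        return float("nan")
    lo, hi = np.percentile(d, percentile_range)
    if lo <= 0 or hi <= lo:
        return float("nan")
    radii = np.geomspace(lo, hi, 12)
    d_sorted = np.sort(d)
    c = np.searchsorted(d_sorted, radii, side="right") / d.size
    good = c > 0
    if good.sum() < 2:
        return float("nan")
    return float(np.polyfit(np.log(radii[good]), np.log(c[good]), 1)[0])
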