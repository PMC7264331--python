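"""Frequency-domain HRV markers (markers 12-24 FFT route, 25-37 AR route).

The unevenly sampled tachogram RR(t) is cubic-spline interpolated at 4 Hz.
The FFT route is a Welch periodogram (300 s Hann segments, 50% overlap);
the autoregressive route is a Burg model of order 16 whose parametric
spectrum is integrated per band.  Band edges follow the standard
ESC/NASPE convention: VLF <= 0.04 Hz, LF (0.04, 0.15] Hz, HF (0.15, 0.4] Hz;
total power is the 0-0.4 Hz integral, so the three relative powers sum to
100 exactly.  Powers are in ms^2 (the tachogram is interpolated in ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch
from statsmodels.regression.linear_model import burg

from ..rr import RRSeries

RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 300.0
AR_ORDER = 16
VLF_EDGE = 0.04
LF_EDGE = 0.15
HF_EDGE = 0.40
MIN_DURATION_S = 300.0


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density of the tachogram.

    frequencies in Hz (strictly increasing), power_density in ms^2/Hz,
    method is "fft" (Welch) or "ar" (Burg).
    """

    frequencies: np.ndarray
    power_density: np.ndarray
    method: str

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        p = np.asarray(self.power_density, float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power density must be non-negative")


def resample_tachogram(series: RRSeries, fs: float = RESAMPLE_HZ) -> np.ndarray:
    """Evenly sampled RR(t) in milliseconds at rate ``fs``.

    RR_n is attached to its end beat time t_{n+1} and interpolated with a
    cubic spline over a regular grid spanning the recording.
    """
    t = series.beat_times[1:]
    rr_ms = series.intervals * 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return CubicSpline(t, rr_ms)(grid)


def estimate_spectrum(series: RRSeries, method: str = "fft") -> SpectralEstimate:
    """Tachogram PSD by Welch ("fft") or Burg AR ("ar")."""
    if series.duration < MIN_DURATION_S:
        raise ValueError("need at least 5 minutes of data for spectral markers")
    x = resample_tachogram(series)
    if method == "fft":
        nperseg = min(int(WELCH_SEGMENT_S * RESAMPLE_HZ), x.size)
        f, p = welch(x, fs=RESAMPLE_HZ, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")
        # drop the DC bin: mean level is not HRV power
        return SpectralEstimate(f[1:], p[1:], "fft")
    if method == "ar":
        xc = x - x.mean()
        rho, sigma2 = burg(xc, order=AR_ORDER)
        f = np.linspace(0.0, RESAMPLE_HZ / 2.0, 2048)[1:]
        z = np.exp(-2j * np.pi * np.outer(f, np.arange(1, AR_ORDER + 1)) / RESAMPLE_HZ)
        denom = np.abs(1.0 - z @ rho) ** 2
        # one-sided parametric PSD
        p = 2.0 * sigma2 / (RESAMPLE_HZ * denom)
        return SpectralEstimate(f, p, "ar")
    raise ValueError(f"unknown spectral method {method!r}")


def band_quantities(est: SpectralEstimate) -> dict[str, float]:
    """Peaks (Hz) and rectangular-rule powers (ms^2) for VLF/LF/HF."""
    f, p = est.frequencies, est.power_density
    df = f[1] - f[0] if f.size > 1 else 1.0
    bands = {
        "vlf": f <= VLF_EDGE,
        "lf": (f > VLF_EDGE) & (f <= LF_EDGE),
        "hf": (f > LF_EDGE) & (f <= HF_EDGE),
    }
    out: dict[str, float] = {}
    for name, mask in bands.items():
        if not mask.any():
            out[f"{name}_peak"] = float("nan")
            out[f"{name}_power"] = 0.0
            continue
        out[f"{name}_peak"] = float(f[mask][np.argmax(p[mask])])
        out[f"{name}_power"] = float(np.sum(p[mask]) * df)
    out["total_power"] = out["vlf_power"] + out["lf_power"] + out["hf_power"]
    return out


def spectral_markers(series: RRSeries, method: str = "fft") -> dict[int, float]:
    """Markers 12-24 (method="fft") or 25-37 (method="ar"), keyed by index.

    Per band: peak frequency, absolute power, relative power (% of total);
    normalized LF and HF are percentages of LF+HF, so they sum to 100;
    the final pair is total power and the LF/HF absolute-power ratio.
    """
    est = estimate_spectrum(series, method)
    q = band_quantities(est)
    total = q["total_power"]
    lf, hf = q["lf_power"], q["hf_power"]
    if total <= 0 or (lf + hf) <= 0:
        raise ZeroDivisionError("zero spectral power; band ratios undefined")
    base = 12 if method == "fft" else 25
    vals = [
        q["vlf_peak"],
        q["vlf_power"],
        100.0 * q["vlf_power"] / total,
        q["lf_peak"],
        lf,
        100.0 * lf / total,
        100.0 * lf / (lf + hf),
        q["hf_peak"],
        hf,
        100.0 * hf / total,
        100.0 * hf / (lf + hf),
        total,
        lf / hf if hf > 0 else float("inf"),
    ]
    return {base + i: float(v) for i, v in enumerate(vals)}
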