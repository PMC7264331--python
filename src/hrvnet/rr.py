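"""RR-interval series: data model, I/O and descriptive statistics.

The raw object of study is the tachogram — the ordered sequence of
beat-to-beat (RR) intervals extracted from a Holter recording.  Intervals
are stored in seconds; a millisecond flag is provided on input because HRV
conventions mix the two units (mean RR in s, the NN50 threshold in ms).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Recognised patient class tags.
CLASS_LABELS = ("H", "AF", "CD", "DIAB", "TIR", "TENS", "O", "unknown")


class RRParseError(ValueError):
    """Raised when an RR file contains a non-numeric or non-positive entry."""


@dataclass(frozen=True)
class RRSeries:
    """A labelled sequence of beat-to-beat intervals, in seconds.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    intervals : numpy.ndarray
        Ordered RR intervals in seconds; all finite and positive, length >= 2.
    label : str
        Class tag from :data:`CLASS_LABELS`.
    """

    patient_id: str
    intervals: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("RRSeries needs at least 2 intervals (one beat pair)")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("RR intervals must be finite and strictly positive")
        object.__setattr__(self, "intervals", arr)
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Total recording span covered by the intervals, in seconds."""
        return float(self.intervals.sum())

    @property
    def beat_times(self) -> np.ndarray:
        """Beat times t_n with t_1 = 0, so RR_n = t_{n+1} - t_n."""
        t = np.empty(self.intervals.size + 1)
        t[0] = 0.0
        np.cumsum(self.intervals, out=t[1:])
        return t


@dataclass(frozen=True)
class BPMSeries:
    """Beats-per-minute counts, one per whole elapsed minute."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if np.any(arr < 0):
            raise ValueError("BPM counts must be non-negative")
        object.__setattr__(self, "counts", arr)


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey box-plot statistics with 1.5 IQR fences on both sides."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))


def load_rr_series(
    path: str | Path,
    dialect: str = "plain",
    *,
    patient_id: str | None = None,
    label: str = "unknown",
    milliseconds: bool = False,
) -> RRSeries:
    """Read an RR series from disk.

    ``plain`` files carry one RR value per line (seconds unless
    ``milliseconds=True``); ``csv`` files carry a header
    ``patient_id,rr_seconds,label``.
    """
    path = Path(path)
    if dialect not in ("plain", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    values: list[float] = []
    if dialect == "plain":
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    v = float(raw)
                except ValueError as exc:
                    raise RRParseError(f"{path}:{lineno}: non-numeric entry {raw!r}") from exc
                if v <= 0:
                    raise RRParseError(f"{path}:{lineno}: non-positive RR value {v}")
                values.append(v)
        pid = patient_id if patient_id is not None else path.stem
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            pid, lab = patient_id, None
            for lineno, row in enumerate(reader, start=2):
                try:
                    v = float(row["rr_seconds"])
                except (TypeError, ValueError) as exc:
                    raise RRParseError(f"{path}:{lineno}: non-numeric entry") from exc
                if v <= 0:
                    raise RRParseError(f"{path}:{lineno}: non-positive RR value {v}")
                values.append(v)
                pid = pid or row.get("patient_id") or path.stem
                lab = lab or row.get("label")
            if lab:
                label = lab
        pid = pid or path.stem
    if not values:
        raise RRParseError(f"{path}: empty RR file")
    arr = np.asarray(values)
    if milliseconds:
        arr = arr / 1000.0
    return RRSeries(patient_id=pid, intervals=arr, label=label)


def write_rr_series(series: RRSeries, path: str | Path, dialect: str = "plain") -> None:
    """Write a series in a format :func:`load_rr_series` reads back identically."""
    path = Path(path)
    if dialect == "plain":
        path.write_text("".join(f"{v:.17g}\n" for v in series.intervals))
    elif dialect == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "rr_seconds", "label"])
            for v in series.intervals:
                w.writerow([series.patient_id, f"{v:.17g}", series.label])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_cohort(cohort: Sequence[RRSeries], directory: str | Path) -> Path:
    """Write one plain RR file per patient plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort:
        fname = f"{s.patient_id}.rr"
        write_rr_series(s, directory / fname)
        entries.append({"patient_id": s.patient_id, "file": fname, "label": s.label})
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"patients": entries}, indent=1, sort_keys=True))
    return manifest


def load_cohort(manifest_path: str | Path) -> list[RRSeries]:
    """Load every series referenced by a cohort manifest."""
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    out = []
    for e in spec["patients"]:
        out.append(
            load_rr_series(
                manifest_path.parent / e["file"],
                patient_id=e["patient_id"],
                label=e["label"],
            )
        )
    return out


def derive_bpm(series: RRSeries) -> BPMSeries:
    """Count RR intervals completing inside each successive 60 s window.

    Windows are non-overlapping and anchored at the first beat (t_1 = 0); an
    interval belongs to the window containing its end time t_{n+1}.  The
    trailing partial minute is discarded.
    """
    ends = series.beat_times[1:]
    n_minutes = int(ends[-1] // 60.0)
    if n_minutes == 0:
        warnings.warn("series shorter than one minute; empty BPM series", stacklevel=2)
        return BPMSeries(counts=np.empty(0, dtype=int))
    # interval n ends at t_{n+1}; window m covers (60m, 60(m+1)]
    idx = np.ceil(ends / 60.0).astype(int) - 1
    inside = idx < n_minutes
    counts = np.bincount(idx[inside], minlength=n_minutes)
    return BPMSeries(counts=counts)


def summarize_distribution(values: Iterable[float]) -> BoxplotSummary:
    """Tukey box-plot summary: quartiles, 1.5 IQR whiskers, outliers.

    Quartiles use linear interpolation between order statistics.  Outliers
    fall outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; whiskers extend to the most
    extreme non-outlier values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values for a box-plot summary")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (arr >= lo) & (arr <= hi)
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(arr[mask].min()),
        whisker_high=float(arr[mask].max()),
        outliers=np.sort(arr[~mask]),
    )
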