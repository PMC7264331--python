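"""Assembly of the full 49-marker patient vector and a sklearn transformer.

A patient's coarse-grained state is the vector of 49 HRV markers: 11
time-domain, 13 FFT-route and 13 AR-route spectral, and 12 non-linear
quantities.  Markers whose data requirements a series does not meet are
recorded as absent (NaN), never as zero; imputation is a downstream,
cohort-level concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..rr import RRSeries
from . import nonlinear, spectral, time_domain

MARKER_NAMES: tuple[str, ...] = (
    "Mean RR", "SDNN", "Mean HR", "STDHR", "RMSSD", "NN50", "pNN50",
    "HRV TIN", "TINN", "SDNN index", "SDANN",
    "VLF peak (FFT)", "Absolute Power VLF (FFT)", "Relative Power VLF (FFT)",
    "LF peak (FFT)", "Absolute Power LF (FFT)", "Relative Power LF (FFT)",
    "Normalized Power LF (FFT)", "HF peak (FFT)", "Absolute Power HF (FFT)",
    "Relative Power HF (FFT)", "Normalized Power HF (FFT)", "Total Power (FFT)",
    "LF/HF (FFT)",
    "VLF peak (AR)", "Absolute Power VLF (AR)", "Relative Power VLF (AR)",
    "LF peak (AR)", "Absolute Power LF (AR)", "Relative Power LF (AR)",
    "Normalized Power LF (AR)", "HF peak (AR)", "Absolute Power HF (AR)",
    "Relative Power HF (AR)", "Normalized Power HF (AR)", "Total Power (AR)",
    "LF/HF (AR)",
    "SD1", "SD2", "RPL mean", "RPL max", "REC", "DET", "ShanEn",
    "ApEn", "SampEn", "DFA alpha1", "DFA alpha2", "D2",
)

MARKER_UNITS: tuple[str, ...] = (
    "s", "s", "bpm", "bpm", "s", "count", "%", "", "s", "s", "s",
    "Hz", "ms^2", "%", "Hz", "ms^2", "%", "%", "Hz", "ms^2", "%", "%", "ms^2", "",
    "Hz", "ms^2", "%", "Hz", "ms^2", "%", "%", "Hz", "ms^2", "%", "%", "ms^2", "",
    "s", "s", "beats", "beats", "%", "%", "nats", "", "", "", "", "",
)

COLUMNS: tuple[str, ...] = tuple(f"m{i:02d}" for i in range(1, 50))


@dataclass(frozen=True)
class MarkerConfig:
    """Tunable parameters of the marker battery."""

    rqa_m: int = 10
    rqa_tau: int = 1
    rqa_l_min: int = 2
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    d2_m: int = 10
    d2_tau: int = 1


@dataclass(frozen=True)
class MarkerVector:
    """The 49 markers of one patient, indexed 1..49; NaN marks absent values."""

    patient_id: str
    label: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (49,):
            raise ValueError("a marker vector has exactly 49 entries")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, index: int) -> float:
        """Value of marker ``index`` in 1-based Table numbering."""
        return float(self.values[index - 1])

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


def marker_vector(series: RRSeries, config: MarkerConfig = MarkerConfig()) -> MarkerVector:
    """Compute all 49 markers; data-starved markers come back NaN (absent)."""
    vals = np.full(49, np.nan)

    def put(d: dict[int, float]) -> None:
        for k, v in d.items():
            vals[k - 1] = v

    put(time_domain.time_domain_markers(series))
    for method in ("fft", "ar"):
        try:
            put(spectral.spectral_markers(series, method))
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"{series.patient_id}: spectral ({method}) absent: {exc}",
                          stacklevel=2)
    try:
        put(nonlinear.poincare_markers(series))
    except ValueError:
        pass
    try:
        put(nonlinear.recurrence_markers(series, m=config.rqa_m, tau=config.rqa_tau,
                                         l_min=config.rqa_l_min))
    except ValueError:
        pass
    try:
        vals[44] = nonlinear.approximate_entropy(series, config.entropy_m,
                                                 config.entropy_r_factor)
        vals[45] = nonlinear.sample_entropy(series, config.entropy_m,
                                            config.entropy_r_factor)
    except ValueError:
        pass
    try:
        put(nonlinear.dfa_alphas(series))
    except ValueError:
        pass
    try:
        vals[48] = nonlinear.correlation_dimension(series, config.d2_m, config.d2_tau)
    except ValueError:
        pass
    return MarkerVector(patient_id=series.patient_id, label=series.label, values=vals)


def marker_table(cohort: list[RRSeries], config: MarkerConfig = MarkerConfig(),
                 progress: bool = False) -> pd.DataFrame:
    """Marker matrix for a cohort: one row per patient, columns label, m01..m49."""
    rows, ids, labels = [], [], []
    iterator = cohort
    if progress:
        from tqdm import tqdm  # optional nicety for interactive runs

        iterator = tqdm(cohort, desc="markers")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in iterator:
            mv = marker_vector(s, config)
            rows.append(mv.values)
            ids.append(s.patient_id)
            labels.append(s.label)
    df = pd.DataFrame(np.vstack(rows), columns=list(COLUMNS),
                      index=pd.Index(ids, name="patient_id"))
    df.insert(0, "label", labels)
    return df


class HRVMarkerExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: list of RR series -> 49-column matrix.

    ``transform`` returns a (n_patients, 49) float array with NaN for absent
    markers; :meth:`transform_frame` keeps patient ids and labels.
    """

    def __init__(self, rqa_m: int = 10, rqa_tau: int = 1, rqa_l_min: int = 2,
                 entropy_m: int = 2, entropy_r_factor: float = 0.2,
                 d2_m: int = 10, d2_tau: int = 1):
        self.rqa_m = rqa_m
        self.rqa_tau = rqa_tau
        self.rqa_l_min = rqa_l_min
        self.entropy_m = entropy_m
        self.entropy_r_factor = entropy_r_factor
        self.d2_m = d2_m
        self.d2_tau = d2_tau

    def _config(self) -> MarkerConfig:
        return MarkerConfig(self.rqa_m, self.rqa_tau, self.rqa_l_min,
                            self.entropy_m, self.entropy_r_factor,
                            self.d2_m, self.d2_tau)

    def fit(self, X: list[RRSeries], y=None) -> "HRVMarkerExtractor":
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[RRSeries]) -> np.ndarray:
        return self.transform_frame(X)[list(COLUMNS)].to_numpy()

    def transform_frame(self, X: list[RRSeries]) -> pd.DataFrame:
        return marker_table(list(X), self._config())

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(COLUMNS, dtype=object)
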