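"""Cohort-level marker statistics.

Standardization (population 1/M convention), Pearson correlation between
markers, redundancy-driven reduction of the 49 markers to 41, class
conditional joint distributions, and PCA on the standardized matrix.

The redundancy analysis flags marker pairs whose Pearson coefficient
exceeds 0.990 in magnitude.  Three of those pairs are analytically forced:
SD1 is RMSSD/sqrt(2) exactly, and each route's normalized LF and HF powers
sum to 100, so (5, 38) correlate at +1 and (18, 22) and (31, 35) at -1 on
any cohort.  The default drop list removes markers 22, 27, 29, 31, 33, 34,
35 and 38, leaving the 41 classifier inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .markers.extract import COLUMNS

REDUNDANCY_THRESHOLD = 0.990
#: Markers discarded by the redundancy analysis (Table 3-5 numbering).
DEFAULT_DROP_LIST: tuple[int, ...] = (22, 27, 29, 31, 33, 34, 35, 38)


def marker_columns(df: pd.DataFrame) -> list[str]:
    """The mNN marker columns of a marker table, in order."""
    return [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]


def impute_missing(df: pd.DataFrame, means: pd.Series | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Replace absent (NaN) markers with per-column means.

    ``means`` supplies training-set means when transforming held-out data;
    otherwise means are taken from ``df`` itself.  Returns the imputed frame
    and the means used.
    """
    cols = marker_columns(df)
    if means is None:
        means = df[cols].mean(skipna=True)
    out = df.copy()
    out[cols] = out[cols].fillna(means)
    return out, means


def standardize(df: pd.DataFrame, center: pd.Series | None = None,
                scale: pd.Series | None = None
                ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise standardization with the population (1/M) SD convention.

    Zero-variance columns are only centered (scale forced to 1) and left at
    zero rather than producing NaN.
    """
    cols = marker_columns(df)
    x = df[cols]
    if center is None:
        center = x.mean()
        scale = x.std(ddof=0).replace(0.0, 1.0)
    out = df.copy()
    out[cols] = (x - center) / scale
    return out, center, scale


def pearson_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Full symmetric Pearson correlation matrix over marker columns.

    Columns with zero variance yield NaN correlations (recorded as absent).
    """
    cols = marker_columns(df)
    if len(df) < 3:
        raise ValueError("need at least 3 patients for a correlation matrix")
    return df[cols].corr(method="pearson")


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson matrix plus the redundant pairs and resulting drop list."""

    matrix: pd.DataFrame
    redundant_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    drop_list: tuple[int, ...] = ()


def find_redundant_pairs(matrix: pd.DataFrame,
                         threshold: float = REDUNDANCY_THRESHOLD
                         ) -> list[tuple[int, int, float]]:
    """Unordered marker pairs with |C_ij| >= threshold, by descending |C_ij|."""
    cols = list(matrix.columns)
    pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            c = matrix.iloc[a, b]
            if np.isfinite(c) and abs(c) >= threshold:
                pairs.append((int(cols[a][1:]), int(cols[b][1:]), float(c)))
    pairs.sort(key=lambda p: -abs(p[2]))
    return pairs


def resolve_drop_list(pairs: list[tuple[int, int, float]],
                      mode: str = "paper_default") -> tuple[int, ...]:
    """Markers to discard so that no redundant pair survives.

    ``paper_default`` returns the fixed eight-marker list
    :data:`DEFAULT_DROP_LIST`.  ``greedy`` iteratively drops the marker in
    the most remaining pairs (ties resolved toward the higher index).
    """
    if mode == "paper_default":
        return DEFAULT_DROP_LIST
    if mode != "greedy":
        raise ValueError(f"unknown mode {mode!r}")
    remaining = [(i, j) for i, j, _ in pairs]
    dropped: list[int] = []
    while remaining:
        counts: dict[int, int] = {}
        for i, j in remaining:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        best = max(counts, key=lambda k: (counts[k], k))
        dropped.append(best)
        remaining = [p for p in remaining if best not in p]
    return tuple(sorted(dropped))


def correlation_report(df: pd.DataFrame,
                       threshold: float = REDUNDANCY_THRESHOLD,
                       mode: str = "paper_default") -> CorrelationReport:
    matrix = pearson_matrix(df)
    pairs = find_redundant_pairs(matrix, threshold)
    return CorrelationReport(matrix=matrix, redundant_pairs=pairs,
                             drop_list=resolve_drop_list(pairs, mode))


def reduce_markers(df: pd.DataFrame,
                   drop_list: tuple[int, ...] = DEFAULT_DROP_LIST) -> pd.DataFrame:
    """Remove the listed markers; remaining columns keep their numbering."""
    cols = marker_columns(df)
    known = {int(c[1:]) for c in cols}
    unknown = set(drop_list) - known
    if unknown:
        raise KeyError(f"drop list contains unknown marker indices {sorted(unknown)}")
    return df.drop(columns=[f"m{i:02d}" for i in drop_list])


class RedundancyReducer(BaseEstimator, TransformerMixin):
    """Sklearn transformer dropping redundant markers from a 49-column matrix.

    With ``mode="paper_default"`` the fixed eight-marker list is applied;
    with ``mode="greedy"`` the drop list is derived from the training data's
    own redundant pairs.
    """

    def __init__(self, mode: str = "paper_default",
                 threshold: float = REDUNDANCY_THRESHOLD):
        self.mode = mode
        self.threshold = threshold

    def fit(self, X, y=None) -> "RedundancyReducer":
        X = np.asarray(X, dtype=float)
        if self.mode == "paper_default":
            self.drop_list_ = DEFAULT_DROP_LIST
        else:
            df = pd.DataFrame(X, columns=list(COLUMNS[: X.shape[1]]))
            self.drop_list_ = resolve_drop_list(
                find_redundant_pairs(pearson_matrix(df), self.threshold), self.mode
            )
        self.keep_idx_ = np.array(
            [i for i in range(X.shape[1]) if (i + 1) not in self.drop_list_]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.keep_idx_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"m{i + 1:02d}" for i in self.keep_idx_], dtype=object)


def joint_histogram(df: pd.DataFrame, class_tag: str, i: int, j: int,
                    bins: int = 40) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2-D joint density of markers i and j within one class.

    Bin edges span the class-pooled 1st-99th percentile range of each
    marker; the returned histogram sums to 1.
    """
    ci, cj = f"m{i:02d}", f"m{j:02d}"
    sub = df.loc[df["label"] == class_tag, [ci, cj]].dropna()
    if sub.empty:
        raise ValueError(f"class {class_tag!r} has no members")
    pooled = df[[ci, cj]].dropna()
    edges_i = np.linspace(*np.percentile(pooled[ci], [1, 99]), bins + 1)
    edges_j = np.linspace(*np.percentile(pooled[cj], [1, 99]), bins + 1)
    h, _, _ = np.histogram2d(np.clip(sub[ci], edges_i[0], edges_i[-1]),
                             np.clip(sub[cj], edges_j[0], edges_j[-1]),
                             bins=(edges_i, edges_j))
    return h / h.sum(), edges_i, edges_j


@dataclass(frozen=True)
class PCAModel:
    """Standardization constants plus orthonormal rotation of a marker matrix."""

    center: np.ndarray
    scale: np.ndarray
    rotation: np.ndarray  # columns are components, by descending variance
    explained_variance_fraction: np.ndarray

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Project standardized rows onto the principal components."""
        return np.asarray(x, dtype=float) @ self.rotation

    def back_rotate(self, scores: np.ndarray) -> np.ndarray:
        """Return scores to the standardized marker space."""
        return np.asarray(scores, dtype=float) @ self.rotation.T


def fit_pca(x: np.ndarray) -> PCAModel:
    """Full-rank PCA of an already-standardized matrix.

    Sign convention: the largest-magnitude loading of each component is
    positive, so rotations are reproducible across BLAS builds.
    """
    x = np.asarray(x, dtype=float)
    p = PCA(n_components=min(x.shape))
    p.fit(x)
    rot = p.components_.T.copy()
    flip = np.sign(rot[np.abs(rot).argmax(axis=0), np.arange(rot.shape[1])])
    rot *= flip
    return PCAModel(
        center=x.mean(axis=0),
        scale=x.std(axis=0),
        rotation=rot,
        explained_variance_fraction=p.explained_variance_ratio_.copy(),
    )
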