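"""PCA-soiling data augmentation for tabular marker matrices.

New marker vectors are synthesized by multiplying each row's first
principal-component score by an independent factor alpha drawn uniformly
from (1 - eps/2, 1 + eps/2) with 0 < eps < 1, keeping the remaining scores,
and back-rotating to the standardized marker space.  Each source row yields
``copies_per_example`` perturbed copies (the output contains only the
copies, so 2300 rows at 20 copies give 46000 points); at the defaults
eps = 0.1, copies = 20 the per-marker distributions are essentially
unchanged, which is what makes the scheme safe for classifier pre-training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .stats import PCAModel, fit_pca


@dataclass(frozen=True)
class AugmentationConfig:
    """epsilon: perturbation amplitude in (0, 1); copies_per_example; seed."""

    epsilon: float = 0.1
    copies_per_example: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.copies_per_example < 1:
            raise ValueError("copies_per_example must be >= 1")


def pca_soil(x: np.ndarray, model: PCAModel, config: AugmentationConfig,
             y: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Augment a standardized matrix by perturbing first-component scores.

    Returns (augmented matrix, inherited labels or None, source-row index).
    Output rows are grouped by copy: all rows' first copies, then all
    second copies, and so on; rows = copies_per_example x input rows.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(config.seed)
    scores = model.scores(x)
    n, c = x.shape[0], config.copies_per_example
    alphas = rng.uniform(1.0 - config.epsilon / 2.0, 1.0 + config.epsilon / 2.0,
                         size=(c, n))
    tiled = np.tile(scores, (c, 1))
    tiled[:, 0] *= alphas.ravel()
    out = model.back_rotate(tiled)
    provenance = np.tile(np.arange(n), c)
    labels = None if y is None else np.tile(np.asarray(y), c)
    return out, labels, provenance


class PCASoiler(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`pca_soil`.

    ``fit`` learns the PCA rotation from (already standardized) training
    rows; ``sample`` emits the augmented matrix.  A pre-fitted
    :class:`~hrvnet.stats.PCAModel` may be injected instead via
    ``pca_model``.
    """

    def __init__(self, epsilon: float = 0.1, copies_per_example: int = 20,
                 seed: int = 0, pca_model: PCAModel | None = None):
        self.epsilon = epsilon
        self.copies_per_example = copies_per_example
        self.seed = seed
        self.pca_model = pca_model

    def fit(self, X, y=None) -> "PCASoiler":
        self.model_ = self.pca_model if self.pca_model is not None else fit_pca(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def sample(self, X, y=None) -> tuple[np.ndarray, np.ndarray | None]:
        if not hasattr(self, "model_"):
            raise RuntimeError("PCASoiler.sample called before fit")
        cfg = AugmentationConfig(self.epsilon, self.copies_per_example, self.seed)
        out, labels, _ = pca_soil(X, self.model_, cfg, y)
        return out, labels
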