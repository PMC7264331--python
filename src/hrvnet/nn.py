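"""Modular feed-forward classifier for reduced HRV marker vectors.

Three identical binary blocks (H/NH, AF/NAF, CD/NCD) share one
architecture: 41 inputs, three hidden layers of 256, 512 and 1024
exponential-linear units each preceded by multiplicative Gaussian dropout
(rate 0.2), batch normalization after the last hidden layer, and two
softmax outputs.  Training minimizes the categorical cross-entropy
L = -sum_i t_i ln f(s_i) by mini-batch stochastic gradient descent with
Nesterov momentum, in two phases: a pre-training phase on PCA-soiled
augmented data (one freshly sampled large batch per epoch) followed by
training on the real examples.

Everything is implemented directly on numpy float32 arrays; a fixed seed
gives bit-reproducible single-threaded runs.

Probability pairs are ordered (negative class, positive class) throughout,
and argmax ties break toward the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class BlockArchitecture:
    input_width: int = 41
    hidden_widths: tuple[int, ...] = (256, 512, 1024)
    dropout_rate: float = 0.2  # Gaussian dropout: noise SD = sqrt(rate/(1-rate))
    output_width: int = 2


@dataclass(frozen=True)
class TrainingSchedule:
    pretrain_epochs: int = 50
    pretrain_batch: int = 2000
    train_epochs: int = 700
    train_batch: int = 300
    learning_rate: float = 0.01
    momentum: float = 0.9
    nesterov: bool = True
    seed: int = 0

    @staticmethod
    def reduced(seed: int = 0, train_epochs: int = 200) -> "TrainingSchedule":
        """The scaled-down schedule used for desk-scale experiments."""
        return TrainingSchedule(train_epochs=train_epochs, seed=seed)


@dataclass
class TrainingHistory:
    """Per-epoch loss and categorical accuracy, with a phase tag per epoch."""

    phase: list[str] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probabilities: np.ndarray, one_hot_target: np.ndarray) -> float:
    """Mean categorical cross-entropy, probabilities floored at 1e-12."""
    p = np.clip(np.asarray(probabilities, dtype=float), PROB_FLOOR, 1.0)
    t = np.asarray(one_hot_target, dtype=float)
    return float(-(t * np.log(p)).sum(axis=-1).mean())


def categorical_accuracy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of argmax predictions matching binary labels (0 = negative).

    An exact tie predicts the negative class.
    """
    p = np.atleast_2d(probabilities)
    if p.shape[0] == 0:
        raise ValueError("cannot score an empty set")
    pred = (p[:, 1] > p[:, 0]).astype(int)
    return float(np.mean(pred == np.asarray(labels)))


class ClassifierBlock:
    """One binary feed-forward block; weights live in plain numpy arrays."""

    def __init__(self, arch: BlockArchitecture = BlockArchitecture(), seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        widths = (arch.input_width, *arch.hidden_widths)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ELU layers
            self.weights.append(rng.normal(0, scale, (fan_in, fan_out)).astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))
        last = widths[-1]
        scale = np.sqrt(1.0 / last)
        self.w_out = rng.normal(0, scale, (last, arch.output_width)).astype(np.float32)
        self.b_out = np.zeros(arch.output_width, dtype=np.float32)
        # batch-norm parameters and running statistics on the last hidden layer
        self.bn_gamma = np.ones(last, dtype=np.float32)
        self.bn_beta = np.zeros(last, dtype=np.float32)
        self.bn_mean = np.zeros(last, dtype=np.float32)
        self.bn_var = np.ones(last, dtype=np.float32)
        self.bn_momentum = 0.99
        self.bn_eps = 1e-3
        self._velocity = [np.zeros_like(p) for p in self._params()]
        self._rng = rng

    def _params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.w_out, self.b_out,
                self.bn_gamma, self.bn_beta]

    def forward(self, x: np.ndarray, training: bool = False):
        """Probability pairs for a batch; caches intermediates when training."""
        x = np.asarray(x, dtype=np.float32)
        noise_sd = np.sqrt(self.arch.dropout_rate / (1.0 - self.arch.dropout_rate))
        cache = {"inputs": [], "pre": [], "noise": []}
        h = x
        for w, b in zip(self.weights, self.biases):
            if training and self.arch.dropout_rate > 0:
                eta = self._rng.normal(1.0, noise_sd, h.shape).astype(np.float32)
                h = h * eta
                cache["noise"].append(eta)
            else:
                cache["noise"].append(None)
            cache["inputs"].append(h)
            z = h @ w + b
            cache["pre"].append(z)
            h = np.where(z > 0, z, np.expm1(z)).astype(np.float32)  # ELU, alpha=1
        # batch normalization on the last hidden activations
        if training:
            mu = h.mean(axis=0)
            var = h.var(axis=0)
            self.bn_mean = (self.bn_momentum * self.bn_mean
                            + (1 - self.bn_momentum) * mu).astype(np.float32)
            self.bn_var = (self.bn_momentum * self.bn_var
                           + (1 - self.bn_momentum) * var).astype(np.float32)
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_sd = 1.0 / np.sqrt(var + self.bn_eps)
        h_hat = (h - mu) * inv_sd
        y = self.bn_gamma * h_hat + self.bn_beta
        s = y @ self.w_out + self.b_out
        p = softmax(s)
        if training:
            cache.update(h_last=h, h_hat=h_hat, inv_sd=inv_sd, bn_in=y, probs=p)
            self._cache = cache
        return p

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def _backward(self, one_hot: np.ndarray) -> list[np.ndarray]:
        """Gradients of the mean cross-entropy for the cached batch."""
        c = self._cache
        p = c["probs"]
        batch = p.shape[0]
        ds = (p - one_hot).astype(np.float32) / batch
        g_w_out = c["bn_in"].T @ ds
        g_b_out = ds.sum(axis=0)
        dy = ds @ self.w_out.T
        # batch-norm backward (batch statistics)
        g_gamma = (dy * c["h_hat"]).sum(axis=0)
        g_beta = dy.sum(axis=0)
        dh_hat = dy * self.bn_gamma
        m = batch
        dh = c["inv_sd"] / m * (
            m * dh_hat - dh_hat.sum(axis=0)
            - c["h_hat"] * (dh_hat * c["h_hat"]).sum(axis=0)
        )
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            z = self._cache["pre"][layer]
            delu = np.where(z > 0, 1.0, np.exp(z)).astype(np.float32)
            dz = dh * delu
            grads_w.append(self._cache["inputs"][layer].T @ dz)
            grads_b.append(dz.sum(axis=0))
            if layer > 0:
                dh = dz @ self.weights[layer].T
                eta = self._cache["noise"][layer]
                if eta is not None:
                    dh = dh * eta
        grads_w.reverse()
        grads_b.reverse()
        return [*grads_w, *grads_b, g_w_out, g_b_out, g_gamma, g_beta]

    def train_step(self, x: np.ndarray, one_hot: np.ndarray,
                   schedule: TrainingSchedule) -> float:
        """One Nesterov-momentum SGD step; returns the batch loss."""
        p = self.forward(x, training=True)
        loss = cross_entropy(p, one_hot)
        if not np.isfinite(loss):
            raise RuntimeError("training diverged: non-finite loss")
        grads = self._backward(one_hot)
        lr, mom = schedule.learning_rate, schedule.momentum
        for param, vel, g in zip(self._params(), self._velocity, grads):
            vel *= mom
            vel -= lr * g.astype(np.float32)
            if schedule.nesterov:
                param += mom * vel - lr * g.astype(np.float32)
            else:
                param += vel
        return loss


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return out


def _record(history: TrainingHistory, phase: str, block: ClassifierBlock,
            x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray | None, y_val: np.ndarray | None) -> None:
    p = block.predict_proba(x)
    history.phase.append(phase)
    history.train_loss.append(cross_entropy(p, one_hot(y)))
    history.train_accuracy.append(categorical_accuracy(p, y))
    if x_val is not None:
        pv = block.predict_proba(x_val)
        history.val_loss.append(cross_entropy(pv, one_hot(y_val)))
        history.val_accuracy.append(categorical_accuracy(pv, y_val))
    else:
        history.val_loss.append(float("nan"))
        history.val_accuracy.append(float("nan"))


def train_block(
    block: ClassifierBlock,
    pretrain: tuple[np.ndarray, np.ndarray] | None,
    train: tuple[np.ndarray, np.ndarray],
    schedule: TrainingSchedule,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainingHistory:
    """Two-phase optimization of one block; history recorded per epoch.

    Pre-training takes one gradient step per epoch on a freshly sampled
    batch of ``pretrain_batch`` augmented examples; training then iterates
    mini-batches of ``train_batch`` over the real set each epoch.
    """
    rng = np.random.default_rng(schedule.seed)
    history = TrainingHistory()
    x_tr, y_tr = train
    x_val, y_val = validation if validation is not None else (None, None)
    if pretrain is not None:
        x_pre, y_pre = pretrain
        batch = min(schedule.pretrain_batch, len(x_pre))
        for _ in range(schedule.pretrain_epochs):
            idx = rng.choice(len(x_pre), size=batch, replace=False)
            block.train_step(x_pre[idx], one_hot(y_pre[idx]), schedule)
            _record(history, "pretrain", block, x_tr, y_tr, x_val, y_val)
    batch = min(schedule.train_batch, len(x_tr))
    for _ in range(schedule.train_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), batch):
            take = order[start:start + batch]
            block.train_step(x_tr[take], one_hot(y_tr[take]), schedule)
        _record(history, "train", block, x_tr, y_tr, x_val, y_val)
    return history


class BlockClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style binary classifier wrapping one feed-forward block.

    ``fit(X, y)`` accepts optional ``pretrain=(X_aug, y_aug)`` and
    ``validation=(X_val, y_val)`` keyword sets; labels are 0 (negative) / 1
    (positive).  Fitted attributes: ``block_``, ``history_``, ``classes_``.
    """

    def __init__(self, hidden_widths: tuple[int, ...] = (256, 512, 1024),
                 dropout_rate: float = 0.2, pretrain_epochs: int = 50,
                 pretrain_batch: int = 2000, train_epochs: int = 700,
                 train_batch: int = 300, learning_rate: float = 0.01,
                 momentum: float = 0.9, nesterov: bool = True, seed: int = 0):
        self.hidden_widths = hidden_widths
        self.dropout_rate = dropout_rate
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_batch = pretrain_batch
        self.train_epochs = train_epochs
        self.train_batch = train_batch
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.nesterov = nesterov
        self.seed = seed

    def _schedule(self) -> TrainingSchedule:
        return TrainingSchedule(self.pretrain_epochs, self.pretrain_batch,
                                self.train_epochs, self.train_batch,
                                self.learning_rate, self.momentum,
                                self.nesterov, self.seed)

    def fit(self, X, y, pretrain=None, validation=None) -> "BlockClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        arch = BlockArchitecture(input_width=X.shape[1],
                                 hidden_widths=tuple(self.hidden_widths),
                                 dropout_rate=self.dropout_rate)
        self.block_ = ClassifierBlock(arch, seed=self.seed)
        self.history_ = train_block(self.block_, pretrain, (X, y),
                                    self._schedule(), validation)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.block_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return (p[:, 1] > p[:, 0]).astype(int)

    def score(self, X, y, sample_weight=None) -> float:
        return categorical_accuracy(self.predict_proba(X), y)


@dataclass(frozen=True)
class CombinedPrediction:
    """Outcome of the three-block consistency combiner."""

    final_label: str
    consistent: bool
    h_pair: tuple[float, float]
    af_pair: tuple[float, float]
    cd_pair: tuple[float, float]


def combine(h_pair, af_pair, cd_pair) -> CombinedPrediction:
    """Map three (negative, positive) probability pairs to H/AF/CD/O.

    Exactly one positive block names its class; none positive means O;
    any other pattern is inconsistent and falls back to the positive block
    with the highest positive-class probability.
    """
    pairs = {"H": tuple(map(float, h_pair)), "AF": tuple(map(float, af_pair)),
             "CD": tuple(map(float, cd_pair))}
    positives = [lab for lab, (pn, pp) in pairs.items() if pp > pn]
    if len(positives) == 0:
        label, consistent = "O", True
    elif len(positives) == 1:
        label, consistent = positives[0], True
    else:
        label = max(positives, key=lambda lab: pairs[lab][1])
        consistent = False
    return CombinedPrediction(final_label=label, consistent=consistent,
                              h_pair=pairs["H"], af_pair=pairs["AF"],
                              cd_pair=pairs["CD"])
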