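"""End-to-end classification experiments on a marker table.

For a binary task (H/NH, AF/NAF or CD/NCD) each repeat draws a stratified
80/20 split, fits imputation means, standardization constants and the PCA
rotation on the training split only, pre-trains the block on the PCA-soiled
training split and then trains it on the real training rows, recording
per-epoch loss/accuracy curves on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .augment import AugmentationConfig, pca_soil
from .nn import BlockClassifier, TrainingHistory, TrainingSchedule
from .simulate import rearrange_labels
from .stats import (DEFAULT_DROP_LIST, fit_pca, impute_missing, marker_columns,
                    reduce_markers, standardize)

TASKS = {"H/NH": "H", "AF/NAF": "AF", "CD/NCD": "CD"}


@dataclass
class TaskData:
    """Standardized train/validation arrays plus the augmented pre-training pool."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_aug: np.ndarray
    y_aug: np.ndarray
    feature_names: list[str]


def prepare_task_data(
    markers: pd.DataFrame,
    task: str,
    split: float = 0.8,
    seed: int = 0,
    drop_list: tuple[int, ...] = DEFAULT_DROP_LIST,
    augmentation: AugmentationConfig | None = None,
) -> TaskData:
    """Binarize labels for ``task`` and build leakage-free train/val arrays."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    target = TASKS[task]
    reduced = reduce_markers(markers, drop_list)
    labels3 = rearrange_labels(reduced["label"].to_numpy(), target)
    y = (labels3 == target).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"cohort lacks one of the classes for task {task}")
    idx_train, idx_val = train_test_split(
        np.arange(len(reduced)), train_size=split, stratify=y, random_state=seed % (2**32)
    )
    df_train, df_val = reduced.iloc[idx_train], reduced.iloc[idx_val]
    df_train, means = impute_missing(df_train)
    df_val, _ = impute_missing(df_val, means)
    df_train, center, scale = standardize(df_train)
    df_val, _, _ = standardize(df_val, center, scale)
    cols = marker_columns(df_train)
    x_train = df_train[cols].to_numpy()
    x_val = df_val[cols].to_numpy()
    y_train, y_val = y[idx_train], y[idx_val]
    aug_cfg = augmentation or AugmentationConfig(seed=seed)
    model = fit_pca(x_train)
    x_aug, y_aug, _ = pca_soil(x_train, model, aug_cfg, y_train)
    return TaskData(x_train, y_train, x_val, y_val, x_aug, y_aug, cols)


@dataclass
class ExperimentResult:
    """Aggregated curves over repeats, plus per-repeat final validation accuracy."""

    task: str
    histories: list[TrainingHistory] = field(default_factory=list)
    final_val_accuracy: list[float] = field(default_factory=list)

    @property
    def mean_curves(self) -> pd.DataFrame:
        keys = ("train_loss", "train_accuracy", "val_loss", "val_accuracy")
        data = {}
        for k in keys:
            stack = np.array([getattr(h, k) for h in self.histories])
            data[f"{k}_mean"] = stack.mean(axis=0)
            data[f"{k}_sd"] = stack.std(axis=0)
        out = pd.DataFrame(data)
        out.insert(0, "phase", self.histories[0].phase)
        return out


def run_experiment(
    markers: pd.DataFrame,
    task: str,
    repeats: int = 20,
    split: float = 0.8,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    augmentation: AugmentationConfig | None = None,
) -> ExperimentResult:
    """Repeat the split/augment/train cycle and aggregate the learning curves."""
    schedule = schedule or TrainingSchedule()
    result = ExperimentResult(task=task)
    root = np.random.SeedSequence(seed)
    for child in root.spawn(repeats):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        aug_cfg = augmentation or AugmentationConfig(seed=sub_seed)
        data = prepare_task_data(markers, task, split, sub_seed, augmentation=aug_cfg)
        clf = BlockClassifier(
            pretrain_epochs=schedule.pretrain_epochs,
            pretrain_batch=schedule.pretrain_batch,
            train_epochs=schedule.train_epochs,
            train_batch=schedule.train_batch,
            learning_rate=schedule.learning_rate,
            momentum=schedule.momentum,
            nesterov=schedule.nesterov,
            seed=sub_seed,
        )
        clf.fit(data.x_train, data.y_train,
                pretrain=(data.x_aug, data.y_aug),
                validation=(data.x_val, data.y_val))
        result.histories.append(clf.history_)
        result.final_val_accuracy.append(clf.history_.val_accuracy[-1])
    return result


def consistency_audit(pred_af_route: np.ndarray, pred_cd_route: np.ndarray) -> int:
    """Cross-database fault count: AF predictions must be O in the CD route
    and CD predictions O in the AF route."""
    a = np.asarray(pred_af_route)
    c = np.asarray(pred_cd_route)
    faults = np.sum((a == "AF") & (c != "O")) + np.sum((c == "CD") & (a != "O"))
    return int(faults)
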