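"""End-to-end orchestration of the two analysis routes.

Route A: RR series -> 49 markers -> imputation -> redundancy reduction to
41 -> per-task split/standardize/PCA/augment -> three classifier blocks ->
combined four-way H/AF/CD/O predictions with a cross-route consistency
audit.  Route B: per-class DTW similarity graphs and their topological
metric distributions.  Every stochastic stage draws a seed derived
deterministically from the master seed and a stage name, so two runs with
the same configuration are identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, pca_soil
from .experiment import TASKS, prepare_task_data
from .graph import ensemble_metrics
from .markers import marker_table
from .nn import BlockClassifier, TrainingSchedule, combine
from .simulate import CohortConfig, generate_cohort, table_cohort_config
from .stats import DEFAULT_DROP_LIST
from .rr import RRSeries


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 fanned out from the master."""
    h = 17
    for ch in stage:
        h = (h * 31 + ord(ch)) % (2**31)
    return int(np.random.SeedSequence(entropy=master, spawn_key=(h,))
               .generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Single document of every knob an end-to-end run uses."""

    seed: int = 0
    cohort_scale: float = 1.0
    series_length: int = 1000
    epsilon: float = 0.1
    copies_per_example: int = 20
    pretrain_epochs: int = 50
    train_epochs: int = 200
    split: float = 0.8
    drop_list: tuple[int, ...] = DEFAULT_DROP_LIST
    graph_nodes: int = 30
    graph_k: int = 5
    graph_realizations: int = 20
    graph_mode: str = "dtw"
    band_fraction: float = 0.1
    clique_size: int = 3

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def run_route_a(config: RunConfig, cohort: list[RRSeries] | None = None,
                markers: pd.DataFrame | None = None) -> dict:
    """Marker-based route: train all three blocks, combine, audit.

    Returns a JSON-serializable report with per-task validation accuracy,
    four-way combined accuracy on the validation split of the AF task, and
    the cross-database consistency fault count.
    """
    if markers is None:
        if cohort is None:
            cohort = generate_cohort(
                table_cohort_config(stage_seed(config.seed, "cohort"),
                                    config.series_length, config.cohort_scale))
        markers = marker_table(cohort)
    schedule = TrainingSchedule(
        pretrain_epochs=config.pretrain_epochs, train_epochs=config.train_epochs)
    report: dict = {"config": json.loads(config.to_json()), "tasks": {}}
    blocks: dict[str, BlockClassifier] = {}
    shared_seed = stage_seed(config.seed, "split")
    task_data = {}
    for task in TASKS:
        data = prepare_task_data(
            markers, task, config.split, shared_seed,
            drop_list=config.drop_list,
            augmentation=AugmentationConfig(config.epsilon, config.copies_per_example,
                                            stage_seed(config.seed, f"augment:{task}")))
        clf = BlockClassifier(
            pretrain_epochs=schedule.pretrain_epochs,
            train_epochs=schedule.train_epochs,
            seed=stage_seed(config.seed, f"train:{task}"))
        clf.fit(data.x_train, data.y_train, pretrain=(data.x_aug, data.y_aug),
                validation=(data.x_val, data.y_val))
        blocks[task] = clf
        task_data[task] = data
        report["tasks"][task] = {
            "final_train_accuracy": clf.history_.train_accuracy[-1],
            "final_val_accuracy": clf.history_.val_accuracy[-1],
            "final_val_loss": clf.history_.val_loss[-1],
        }
    # combined four-way prediction on the shared validation split
    data = task_data["AF/NAF"]
    probs = {t: blocks[t].predict_proba(task_data[t].x_val) for t in TASKS}
    n_val = len(data.x_val)
    labels4 = []
    consistent = 0
    for i in range(n_val):
        c = combine(probs["H/NH"][i], probs["AF/NAF"][i], probs["CD/NCD"][i])
        labels4.append(c.final_label)
        consistent += int(c.consistent)
    report["combined"] = {
        "n_validation": n_val,
        "consistent_fraction": consistent / n_val,
        "label_counts": pd.Series(labels4).value_counts().to_dict(),
    }
    # cross-database audit: an AF call must look like O to the H/CD/O route
    af_pred = np.asarray(labels4)
    faults = int(np.sum((af_pred == "AF")
                        & (probs["CD/NCD"][:, 1] > probs["CD/NCD"][:, 0])))
    report["combined"]["consistency_faults"] = faults
    return report


def run_route_b(config: RunConfig, cohort: list[RRSeries] | None = None,
                classes: tuple[str, ...] = ("H", "AF", "CD")) -> dict:
    """Graph route: per-class ensemble topology metric summaries."""
    if cohort is None:
        cohort = generate_cohort(
            table_cohort_config(stage_seed(config.seed, "cohort"),
                                config.series_length, config.cohort_scale))
    report: dict = {"config": json.loads(config.to_json()), "classes": {}}
    for tag in classes:
        df = ensemble_metrics(
            cohort, tag, n_nodes=config.graph_nodes, k=config.graph_k,
            realizations=config.graph_realizations,
            seed=stage_seed(config.seed, f"graph:{tag}"),
            mode=config.graph_mode, band_fraction=config.band_fraction,
            clique_size=config.clique_size)
        report["classes"][tag] = {
            c: {"mean": float(df[c].mean()), "sd": float(df[c].std())}
            for c in ("mean_in_degree", "max_in_degree", "in_degree_sd",
                      "gc", "gr", "community_gc_mean")
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
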