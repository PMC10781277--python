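"""Training-condition orchestration and leave-one-subject-out evaluation.

Three training conditions are compared, all evaluated on the stroke group
by default: training on non-disabled participants only (a plain split — no
stroke data in training), training on stroke participants only (LOSO-CV),
and joint training on both groups (LOSO-CV over the stroke participants,
with all non-disabled data always in the pool).  In LOSO-CV one target
participant is held out, a model is trained on everyone else, and the
held-out participant is scored; the per-participant results are then
averaged.  The held-out participant's data never enters training (asserted
per split).

Scoring follows the per-(participant, class) F1 convention: for each
held-out participant, precision and recall are computed one-vs-rest over
that participant's windows for each class, and F1 = 2PR/(P+R) (0 when
P + R = 0).  A segment-level mode (majority vote over each segment's
windows) is available, since windows of one segment are not independent.
Confusion matrices are row-normalized over pooled held-out predictions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .augmentation import RotationSpec, augment_segments, rotate_segment
from .classifier import ModelConfig, TrainConfig, TrainedModel, train
from .io_juimu import Dataset, Segment
from .preprocessing import (
    PreprocessConfig,
    Window,
    preprocess_segment,
    slide_windows,
    stack_windows,
)


@dataclass(frozen=True)
class ConditionSpec:
    """One training condition: who trains, who is evaluated, how."""

    name: str
    training_groups: tuple[str, ...]
    protocol: str  # "split" or "loso"
    eval_group: str = "Stroke"
    augment: bool = False

    def __post_init__(self) -> None:
        if self.protocol not in ("split", "loso"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "split" and self.eval_group in self.training_groups:
            raise ValueError("split protocol requires disjoint train/eval groups")


ND_CONDITION = ConditionSpec("ND", ("ND",), "split")
STROKE_CONDITION = ConditionSpec("Stroke", ("Stroke",), "loso")
JOINT_CONDITION = ConditionSpec("ND+Stroke", ("ND", "Stroke"), "loso")

CONDITIONS = {"nd": ND_CONDITION, "stroke": STROKE_CONDITION, "joint": JOINT_CONDITION}


@dataclass(frozen=True)
class Split:
    train_participants: tuple[str, ...]
    eval_participants: tuple[str, ...]


def loso_splits(dataset: Dataset, condition: ConditionSpec) -> list[Split]:
    """Build the train/eval participant splits for a condition.

    LOSO: one split per eval-group participant, training on the condition's
    groups minus the held-out participant.  Split: a single split, all
    training-group participants vs. all eval-group participants.
    """
    groups: dict[str, str] = {}
    for seg in dataset.segments:
        groups[seg.participant_id] = seg.group
    train_pool = [p for p, g in groups.items() if g in condition.training_groups]
    eval_pool = [p for p, g in groups.items() if g == condition.eval_group]
    if not train_pool or not eval_pool:
        raise ValueError(f"empty participant pool for condition {condition.name!r}")
    if condition.protocol == "split":
        return [Split(tuple(train_pool), tuple(eval_pool))]
    if len(eval_pool) < 2:
        raise ValueError("LOSO requires at least 2 eval-group participants")
    splits = []
    for held_out in eval_pool:
        tr = tuple(p for p in train_pool if p != held_out)
        splits.append(Split(tr, (held_out,)))
    return splits


def f1_per_class(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[int]
) -> dict[int, float]:
    """One-vs-rest F1 per class: 2·TP / (2·TP + FP + FN), 0 on empty."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out: dict[int, float] = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        denom = 2 * tp + fp + fn
        out[c] = (2.0 * tp / denom) if denom else 0.0
    return out


@dataclass
class EvaluationReport:
    """All evaluation outputs of one condition run."""

    condition: ConditionSpec
    classes: list[int]
    class_type_map: dict[int, str]
    #: columns participant_id, group, movement_id, movement_type, f1
    per_participant_class_f1: pd.DataFrame
    #: columns participant_id, group, mean_f1
    per_participant_mean_f1: pd.DataFrame
    #: columns group, mean_f1, sd_f1, min_f1, min_participant, max_f1, max_participant
    group_summary: pd.DataFrame
    #: columns group, movement_type, mean_f1, sd_f1
    movement_type_summary: pd.DataFrame
    #: group -> row-normalized (n_classes x n_classes) matrix
    confusion: dict[str, pd.DataFrame]
    #: group -> ranked off-diagonal (true, inferred, proportion) table
    top_confusion_pairs: dict[str, pd.DataFrame]
    #: raw pooled predictions (participant_id, group, segment_key fields,
    #: window_index, movement_type, y_true, y_pred) for oracle recomputation
    window_predictions: pd.DataFrame
    split_log: list[dict] = field(default_factory=list)


def _predictions_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "movement_id",
            "movement_type",
            "segment_copy",
            "window_index",
            "y_true",
            "y_pred",
        ],
    )


def _majority_vote(labels: np.ndarray) -> int:
    values, counts = np.unique(labels, return_counts=True)
    return int(values[np.argmax(counts)])  # ties -> lowest label


def summarize_predictions(
    predictions: pd.DataFrame,
    classes: Sequence[int],
    class_type_map: Mapping[int, str],
    unit: str = "window",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Aggregate pooled predictions into the report tables.

    ``unit="segment"`` first majority-votes each segment's windows.
    Returns (per-participant-class F1, per-participant means, group
    summary, movement-type summary).
    """
    if unit not in ("window", "segment"):
        raise ValueError(f"unknown unit {unit!r}")
    for m in predictions["y_true"].unique():
        if int(m) not in class_type_map:
            raise KeyError(f"movement {m} missing from class_type_map")
    df = predictions
    if unit == "segment":
        df = (
            df.groupby(["participant_id", "group", "movement_id", "movement_type"])
            .agg(y_true=("y_true", "first"),
                 y_pred=("y_pred", lambda v: _majority_vote(np.asarray(v))))
            .reset_index()
        )
    f1_rows = []
    for (pid, group), part in df.groupby(["participant_id", "group"], sort=True):
        scores = f1_per_class(part["y_true"].to_numpy(), part["y_pred"].to_numpy(), classes)
        for c in classes:
            f1_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "movement_id": c,
                    "movement_type": class_type_map[c],
                    "f1": scores[c],
                }
            )
    per_pc = pd.DataFrame(f1_rows)
    per_participant = (
        per_pc.groupby(["participant_id", "group"])["f1"]
        .mean()
        .reset_index()
        .rename(columns={"f1": "mean_f1"})
    )
    group_rows = []
    for group, part in per_participant.groupby("group"):
        i_min = part["mean_f1"].idxmin()
        i_max = part["mean_f1"].idxmax()
        group_rows.append(
            {
                "group": group,
                "mean_f1": float(part["mean_f1"].mean()),
                "sd_f1": float(part["mean_f1"].std(ddof=0)),
                "min_f1": float(part.loc[i_min, "mean_f1"]),
                "min_participant": part.loc[i_min, "participant_id"],
                "max_f1": float(part.loc[i_max, "mean_f1"]),
                "max_participant": part.loc[i_max, "participant_id"],
            }
        )
    group_summary = pd.DataFrame(group_rows)
    movement_type_summary = (
        per_pc.groupby(["group", "movement_type"])["f1"]
        .agg(mean_f1="mean", sd_f1=lambda v: float(np.std(v, ddof=0)))
        .reset_index()
    )
    return per_pc, per_participant, group_summary, movement_type_summary


def confusion_matrices(
    predictions: pd.DataFrame, classes: Sequence[int], top_k: int = 10
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Row-normalized confusion matrix and top confused pairs per group.

    Rows are true classes, columns model inferences; each populated row
    sums to 1 (rows with no samples stay zero).
    """
    classes = list(classes)
    pos = {c: i for i, c in enumerate(classes)}
    matrices: dict[str, pd.DataFrame] = {}
    pairs: dict[str, pd.DataFrame] = {}
    for group, part in predictions.groupby("group"):
        counts = np.zeros((len(classes), len(classes)))
        for t, p in zip(part["y_true"], part["y_pred"]):
            counts[pos[int(t)], pos[int(p)]] += 1
        sums = counts.sum(axis=1, keepdims=True)
        norm = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
        matrices[group] = pd.DataFrame(norm, index=classes, columns=classes)
        off = [
            {"true": classes[i], "inferred": classes[j], "proportion": norm[i, j]}
            for i in range(len(classes))
            for j in range(len(classes))
            if i != j and norm[i, j] > 0
        ]
        off.sort(key=lambda r: -r["proportion"])
        pairs[group] = pd.DataFrame(
            off[:top_k], columns=["true", "inferred", "proportion"]
        )
    return matrices, pairs


def movement_type_summary(
    report: EvaluationReport | pd.DataFrame,
    class_type_map: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Mean ± sd F1 per (group, movement type) from a per-(participant,
    class) F1 table; recomputable independently of the report."""
    table = (
        report.per_participant_class_f1
        if isinstance(report, EvaluationReport)
        else report.copy()
    )
    if class_type_map is not None:
        unmapped = set(table["movement_id"]) - set(class_type_map)
        if unmapped:
            raise KeyError(f"movements {sorted(unmapped)} missing from class_type_map")
        table = table.assign(
            movement_type=[class_type_map[m] for m in table["movement_id"]]
        )
    return (
        table.groupby(["group", "movement_type"])["f1"]
        .agg(mean_f1="mean", sd_f1=lambda v: float(np.std(v, ddof=0)))
        .reset_index()
    )


def _derived_seed(base: int, *tags: int) -> int:
    return int(
        np.random.SeedSequence([base, *tags]).generate_state(1)[0] % (2**31)
    )


def run_condition(
    dataset: Dataset,
    condition: ConditionSpec,
    pre_config: PreprocessConfig,
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
    rotation_spec: RotationSpec = RotationSpec(),
    unit: str = "window",
    test_rotation_nuisance: bool = False,
    final_relu: bool = False,
) -> EvaluationReport:
    """Run one training condition end to end and assemble its report.

    Preprocessing runs once per segment; each split then trains a fresh
    model (augmenting the training segments with one rotated copy each when
    the condition enables augmentation) and scores its held-out
    participant(s).  ``test_rotation_nuisance`` applies an independent
    random rotation to every evaluation segment, emulating unseen sensor
    orientations at deployment time.  Per-split seeds derive from
    ``train_config.seed`` so any split is re-runnable in isolation.
    """
    classes = sorted({s.movement_id for s in dataset.segments})
    class_type_map = {s.movement_id: s.movement_type for s in dataset.segments}
    if model_config is None:
        model_config = ModelConfig(
            input_length=pre_config.window_size,
            input_channels=pre_config.n_channels,
            n_classes=len(classes),
            final_relu=final_relu,
        )

    processed: dict[str, list[Segment]] = {}
    for seg in dataset.segments:
        processed.setdefault(seg.participant_id, []).append(
            preprocess_segment(seg, pre_config)
        )

    splits = loso_splits(dataset, condition)
    prediction_rows: list[dict] = []
    split_log: list[dict] = []
    for k, split in enumerate(splits):
        overlap = set(split.train_participants) & set(split.eval_participants)
        assert not overlap, f"participant leakage: {overlap}"
        train_segs = [s for p in split.train_participants for s in processed[p]]
        if condition.augment:
            aug_rng = np.random.default_rng(
                _derived_seed(train_config.seed, 71, k)
            )
            train_segs = augment_segments(train_segs, rotation_spec, aug_rng)
        train_windows: list[Window] = []
        for seg in train_segs:
            train_windows.extend(slide_windows(seg, pre_config))
        x_train, y_train = stack_windows(train_windows)
        split_seed = _derived_seed(train_config.seed, 11, k)
        model = train(
            x_train,
            y_train,
            model_config,
            replace(train_config, seed=split_seed),
            classes=classes,
            provenance={
                "condition": condition.name,
                "split": k,
                "train_participants": list(split.train_participants),
            },
        )
        for pid in split.eval_participants:
            eval_segs = processed[pid]
            if test_rotation_nuisance:
                pid_tag = zlib.crc32(pid.encode()) % 2**16  # stable across runs
                nuis_rng = np.random.default_rng(
                    _derived_seed(train_config.seed, 97, k, pid_tag)
                )
                eval_segs = [
                    rotate_segment(s, rotation_spec, nuis_rng) for s in eval_segs
                ]
            eval_windows: list[Window] = []
            for seg in eval_segs:
                eval_windows.extend(slide_windows(seg, pre_config))
            x_eval, y_eval = stack_windows(eval_windows)
            y_pred = model.predict(x_eval)
            for w, yt, yp in zip(eval_windows, y_eval, y_pred):
                prediction_rows.append(
                    {
                        "participant_id": w.participant_id,
                        "group": w.group,
                        "movement_id": w.movement_id,
                        "movement_type": w.movement_type,
                        "segment_copy": w.segment_key[2],
                        "window_index": w.window_index,
                        "y_true": int(yt),
                        "y_pred": int(yp),
                    }
                )
        split_log.append(
            {
                "split": k,
                "train_participants": list(split.train_participants),
                "eval_participants": list(split.eval_participants),
                "seed": split_seed,
                "n_train_windows": len(train_windows),
                "final_loss": model.loss_history[-1],
            }
        )

    predictions = _predictions_frame(prediction_rows)
    per_pc, per_participant, group_summary, type_summary = summarize_predictions(
        predictions, classes, class_type_map, unit=unit
    )
    matrices, pairs = confusion_matrices(predictions, classes)
    return EvaluationReport(
        condition=condition,
        classes=classes,
        class_type_map=class_type_map,
        per_participant_class_f1=per_pc,
        per_participant_mean_f1=per_participant,
        group_summary=group_summary,
        movement_type_summary=type_summary,
        confusion=matrices,
        top_confusion_pairs=pairs,
        window_predictions=predictions,
        split_log=split_log,
    )


def macro_f1(report: EvaluationReport, group: str = "Stroke") -> float:
    """Mean of per-participant mean F1 over one evaluation group."""
    part = report.per_participant_mean_f1
    sel = part[part["group"] == group]
    if sel.empty:
        raise ValueError(f"no evaluated participants in group {group!r}")
    return float(sel["mean_f1"].mean())
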