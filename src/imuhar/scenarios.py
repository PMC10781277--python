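"""Desk-scale study scenarios: fixed configurations for the synthetic
recovery and trend experiments.

These are the package's scaled-down analogues of the full study protocol,
kept small enough to run on one CPU in minutes: segments average 300 time
points (interpolated to 290, cut into the same 20 windows per segment as
the full-scale presets), and training runs 10 epochs with batch size 64 —
the batch is scaled down with the training-set size so the number of
optimizer updates stays proportionate to the full protocol's.

Two scenarios are defined:

* recovery — 8 movement classes (all unimanual), 8 non-disabled + 4 stroke
  participants; pooled (joint) LOSO training should recover held-out
  stroke participants' movements well (macro F1 >= 0.8).
* trend — 9 classes cycling through UNI/BIA/BIS types, 6 non-disabled +
  4 stroke participants, evaluated under a random test-time rotation of
  every evaluation segment (unseen sensor orientations).  Used for the
  directional comparisons: joint vs. stroke-only training, augmentation
  on vs. off, and movement-type F1 ordering in the stroke group.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classifier import TrainConfig
from .evaluation import (
    EvaluationReport,
    JOINT_CONDITION,
    STROKE_CONDITION,
    macro_f1,
    run_condition,
)
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticSpec, generate_dataset

#: small-segment preset: 20 windows per segment, like the full-scale tasks
SMALL_PRE_CONFIG = PreprocessConfig(
    target_length=290, window_size=100, stride=10, windows_per_segment=20
)

SMALL_TRAIN_CONFIG = TrainConfig(epochs=10, batch_size=64)

_SMALL_LENGTHS = dict(length_mean=300.0, length_sd=80.0, length_floor=120)


def recovery_spec(seed: int) -> SyntheticSpec:
    """12-participant, 8-class unimanual dataset at default noise."""
    return SyntheticSpec(
        task="ROM", n_nd=8, n_stroke=4, n_classes=8, seed=seed, **_SMALL_LENGTHS
    )


def trend_spec(seed: int) -> SyntheticSpec:
    """10-participant, 9-class dataset with UNI/BIA/BIS classes."""
    return SyntheticSpec(
        task="ADL", n_nd=6, n_stroke=4, n_classes=9, seed=seed, **_SMALL_LENGTHS
    )


def run_recovery(seed: int) -> tuple[float, EvaluationReport]:
    """Joint (pooled) LOSO training on the recovery scenario.

    Returns the stroke-group macro F1 (mean of held-out participants' mean
    per-class F1) and the full report.
    """
    dataset = generate_dataset(recovery_spec(seed)).dataset
    report = run_condition(
        dataset,
        JOINT_CONDITION,
        SMALL_PRE_CONFIG,
        replace(SMALL_TRAIN_CONFIG, seed=seed),
    )
    return macro_f1(report), report


def run_trend_conditions(seed: int) -> dict[str, EvaluationReport]:
    """Stroke-only, joint, and joint+augmentation runs on the trend
    scenario, all scored under test-time rotational nuisance."""
    dataset = generate_dataset(trend_spec(seed)).dataset
    train_cfg = replace(SMALL_TRAIN_CONFIG, seed=seed)
    out: dict[str, EvaluationReport] = {}
    for name, condition in (
        ("stroke", STROKE_CONDITION),
        ("joint", JOINT_CONDITION),
        ("joint_aug", replace(JOINT_CONDITION, augment=True)),
    ):
        out[name] = run_condition(
            dataset,
            condition,
            SMALL_PRE_CONFIG,
            train_cfg,
            test_rotation_nuisance=True,
        )
    return out


def trend_summary(seeds: list[int]) -> pd.DataFrame:
    """Per-seed condition macro F1 and stroke-group movement-type means.

    Columns: seed, stroke_f1, joint_f1, joint_aug_f1, bis_f1, bia_f1,
    uni_f1 (movement-type means from the joint run).
    """
    rows = []
    for seed in seeds:
        reports = run_trend_conditions(seed)
        types = reports["joint"].movement_type_summary
        stroke_types = types[types["group"] == "Stroke"].set_index("movement_type")
        rows.append(
            {
                "seed": seed,
                "stroke_f1": macro_f1(reports["stroke"]),
                "joint_f1": macro_f1(reports["joint"]),
                "joint_aug_f1": macro_f1(reports["joint_aug"]),
                "uni_f1": float(stroke_types.loc["UNI", "mean_f1"]),
                "bia_f1": float(stroke_types.loc["BIA", "mean_f1"]),
                "bis_f1": float(stroke_types.loc["BIS", "mean_f1"]),
            }
        )
    return pd.DataFrame(rows)
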