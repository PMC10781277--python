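"""LOSO splits, F1 accounting against independent oracles, confusion
matrices, and the end-to-end condition runner."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score as sklearn_f1

from imuhar.evaluation import (
    ConditionSpec,
    JOINT_CONDITION,
    ND_CONDITION,
    STROKE_CONDITION,
    confusion_matrices,
    f1_per_class,
    loso_splits,
    movement_type_summary,
    run_condition,
    summarize_predictions,
)
from imuhar.classifier import TrainConfig
from imuhar.io_juimu import Dataset
from imuhar.preprocessing import PreprocessConfig
from imuhar.synthetic import SyntheticSpec, generate_dataset

from conftest import make_segment


def _marker_dataset(n_nd=3, n_stroke=4):
    """Metadata-only dataset (tiny value blocks) for split logic tests."""
    segments = []
    for i in range(n_nd):
        segments.append(make_segment(np.zeros((4, 45)),
                                     participant_id=f"ND{i+1}", group="ND"))
    for j in range(n_stroke):
        segments.append(
            make_segment(np.zeros((4, 45)), participant_id=f"Stroke{j+1}",
                         group="Stroke",
                         hemiparesis_side="right" if j % 2 == 0 else "left")
        )
    return Dataset(segments=segments)


class TestLosoSplits:
    def test_stroke_loso_yields_one_split_per_patient(self):
        ds = _marker_dataset(n_stroke=14)
        splits = loso_splits(ds, STROKE_CONDITION)
        assert len(splits) == 14
        for split in splits:
            assert len(split.eval_participants) == 1
            assert split.eval_participants[0] not in split.train_participants
            assert all(p.startswith("Stroke") for p in split.train_participants)

    def test_nd_condition_is_a_single_split_without_stroke_training(self):
        ds = _marker_dataset()
        [split] = loso_splits(ds, ND_CONDITION)
        assert sorted(split.train_participants) == ["ND1", "ND2", "ND3"]
        assert all(p.startswith("Stroke") for p in split.eval_participants)

    def test_joint_loso_keeps_all_nd_in_every_pool(self):
        ds = _marker_dataset(n_nd=2, n_stroke=3)
        splits = loso_splits(ds, JOINT_CONDITION)
        assert len(splits) == 3
        for split in splits:
            assert {"ND1", "ND2"} <= set(split.train_participants)
            assert len(split.train_participants) == 2 + 2  # all ND + other strokes

    def test_no_leakage_in_any_split(self):
        ds = _marker_dataset(n_nd=4, n_stroke=5)
        for cond in (ND_CONDITION, STROKE_CONDITION, JOINT_CONDITION):
            for split in loso_splits(ds, cond):
                assert not set(split.train_participants) & set(split.eval_participants)

    def test_loso_requires_two_eval_participants(self):
        ds = _marker_dataset(n_stroke=1)
        with pytest.raises(ValueError):
            loso_splits(ds, STROKE_CONDITION)


class TestF1Accounting:
    def test_perfect_predictions_give_unit_f1(self):
        y = np.repeat(np.arange(1, 15), 20)
        scores = f1_per_class(y, y, list(range(1, 15)))
        assert all(v == 1.0 for v in scores.values())

    def test_constant_predictor_closed_form(self):
        # 14 balanced classes, everything predicted as class 1:
        # precision 1/14, recall 1 -> F1 = 2/15; all other classes 0
        y_true = np.repeat(np.arange(1, 15), 20)
        y_pred = np.ones_like(y_true)
        scores = f1_per_class(y_true, y_pred, list(range(1, 15)))
        assert scores[1] == pytest.approx(2.0 / 15.0, abs=1e-12)
        assert scores[1] == pytest.approx(0.133, abs=5e-4)
        assert all(scores[c] == 0.0 for c in range(2, 15))

    def test_matches_sklearn_on_random_predictions(self, rng):
        classes = list(range(1, 9))
        for _ in range(5):
            y_true = rng.integers(1, 9, size=200)
            y_pred = rng.integers(1, 9, size=200)
            ours = f1_per_class(y_true, y_pred, classes)
            ref = sklearn_f1(y_true, y_pred, labels=classes, average=None,
                             zero_division=0)
            for c, r in zip(classes, ref):
                assert ours[c] == pytest.approx(r, abs=1e-12)


def _predictions(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "movement_id", "movement_type",
                       "segment_copy", "window_index", "y_true", "y_pred"]
    )


class TestSummaries:
    def _random_predictions(self, rng, n_participants=3, n_classes=4, n_windows=10):
        rows = []
        for p in range(n_participants):
            for c in range(1, n_classes + 1):
                for w in range(n_windows):
                    rows.append({
                        "participant_id": f"Stroke{p+1}", "group": "Stroke",
                        "movement_id": c,
                        "movement_type": ["UNI", "BIA", "BIS"][c % 3],
                        "segment_copy": "orig", "window_index": w,
                        "y_true": c, "y_pred": int(rng.integers(1, n_classes + 1)),
                    })
        return _predictions(rows)

    def test_aggregates_match_bruteforce_recomputation(self, rng):
        classes = [1, 2, 3, 4]
        type_map = {c: ["UNI", "BIA", "BIS"][c % 3] for c in classes}
        preds = self._random_predictions(rng)
        per_pc, per_part, group, types = summarize_predictions(
            preds, classes, type_map
        )
        # brute force: recompute every (participant, class) F1 from counts
        for _, row in per_pc.iterrows():
            part = preds[preds["participant_id"] == row["participant_id"]]
            scores = f1_per_class(part["y_true"].to_numpy(),
                                  part["y_pred"].to_numpy(), classes)
            assert row["f1"] == pytest.approx(scores[row["movement_id"]], abs=1e-12)
        for _, row in per_part.iterrows():
            sel = per_pc[per_pc["participant_id"] == row["participant_id"]]["f1"]
            assert row["mean_f1"] == pytest.approx(sel.mean(), abs=1e-12)
        for _, row in types.iterrows():
            sel = per_pc[(per_pc["group"] == row["group"])
                         & (per_pc["movement_type"] == row["movement_type"])]["f1"]
            assert row["mean_f1"] == pytest.approx(sel.mean(), abs=1e-12)

    def test_segment_unit_majority_vote(self):
        rows = []
        # one segment of 5 windows: 3 votes class 2, 2 votes class 1
        for w, pred in enumerate([2, 2, 1, 2, 1]):
            rows.append({"participant_id": "Stroke1", "group": "Stroke",
                         "movement_id": 2, "movement_type": "UNI",
                         "segment_copy": "orig", "window_index": w,
                         "y_true": 2, "y_pred": pred})
        per_pc, _, _, _ = summarize_predictions(
            _predictions(rows), [1, 2], {1: "UNI", 2: "UNI"}, unit="segment"
        )
        f1 = per_pc.set_index("movement_id")["f1"]
        assert f1[2] == 1.0

    def test_unmapped_class_raises(self, rng):
        preds = self._random_predictions(rng)
        with pytest.raises(KeyError):
            summarize_predictions(preds, [1, 2, 3, 4], {1: "UNI"})

    def test_movement_type_summary_matches_manual_grouping(self, rng):
        preds = self._random_predictions(rng)
        classes = [1, 2, 3, 4]
        type_map = {c: ["UNI", "BIA", "BIS"][c % 3] for c in classes}
        per_pc, _, _, types = summarize_predictions(preds, classes, type_map)
        again = movement_type_summary(per_pc)
        pd.testing.assert_frame_equal(
            types.sort_values(["group", "movement_type"]).reset_index(drop=True),
            again.sort_values(["group", "movement_type"]).reset_index(drop=True),
        )


class TestConfusion:
    def test_perfect_classifier_gives_identity_matrix(self):
        rows = []
        for c in (1, 2, 3):
            for w in range(4):
                rows.append({"participant_id": "Stroke1", "group": "Stroke",
                             "movement_id": c, "movement_type": "UNI",
                             "segment_copy": "orig", "window_index": w,
                             "y_true": c, "y_pred": c})
        matrices, pairs = confusion_matrices(_predictions(rows), [1, 2, 3])
        assert np.allclose(matrices["Stroke"].to_numpy(), np.eye(3))
        assert pairs["Stroke"].empty

    def test_rows_are_distributions_and_pairs_exclude_diagonal(self, rng):
        rows = []
        for c in (1, 2, 3):
            for w in range(30):
                rows.append({"participant_id": "Stroke1", "group": "Stroke",
                             "movement_id": c, "movement_type": "UNI",
                             "segment_copy": "orig", "window_index": w,
                             "y_true": c, "y_pred": int(rng.integers(1, 4))})
        matrices, pairs = confusion_matrices(_predictions(rows), [1, 2, 3])
        m = matrices["Stroke"].to_numpy()
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-6)
        assert all(r["true"] != r["inferred"] for _, r in pairs["Stroke"].iterrows())
        assert (pairs["Stroke"]["proportion"].diff().dropna() <= 1e-12).all()


@pytest.fixture(scope="module")
def tiny_report():
    spec = SyntheticSpec(task="ROM", n_nd=2, n_stroke=2, n_classes=3,
                         length_mean=300.0, length_sd=60.0,
                         length_floor=120, seed=4)
    ds = generate_dataset(spec).dataset
    cfg = PreprocessConfig(target_length=290, window_size=100, stride=10,
                           windows_per_segment=20)
    return run_condition(ds, JOINT_CONDITION, cfg,
                         TrainConfig(epochs=1, batch_size=64, seed=0))


class TestRunCondition:
    def test_report_is_internally_consistent(self, tiny_report):
        rep = tiny_report
        assert rep.classes == [1, 2, 3]
        # 2 stroke participants x 3 classes
        assert len(rep.per_participant_class_f1) == 6
        assert set(rep.per_participant_mean_f1["participant_id"]) == {
            "Stroke1", "Stroke2"
        }
        m = rep.confusion["Stroke"].to_numpy()
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-6)
        assert ((rep.per_participant_class_f1["f1"] >= 0)
                & (rep.per_participant_class_f1["f1"] <= 1)).all()

    def test_split_log_records_training_composition(self, tiny_report):
        log = tiny_report.split_log
        assert len(log) == 2
        for entry in log:
            assert len(entry["train_participants"]) == 3  # 2 ND + 1 stroke
            assert entry["n_train_windows"] == 3 * 3 * 20

    def test_augmentation_doubles_training_windows(self):
        spec = SyntheticSpec(task="ROM", n_nd=2, n_stroke=2, n_classes=2,
                             length_mean=300.0, length_sd=60.0,
                             length_floor=120, seed=4)
        ds = generate_dataset(spec).dataset
        cfg = PreprocessConfig(target_length=290, window_size=100, stride=10,
                               windows_per_segment=20)
        cond = ConditionSpec("ND+Stroke", ("ND", "Stroke"), "loso", augment=True)
        rep = run_condition(ds, cond, cfg, TrainConfig(epochs=1, batch_size=64))
        for entry in rep.split_log:
            assert entry["n_train_windows"] == 2 * (3 * 2 * 20)
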