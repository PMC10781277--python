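"""Synthetic IMU movement generator.

Emulates the statistical structure of the study's recordings so the whole
pipeline is testable offline: two participant groups (non-disabled and
stroke, the latter with a hemiparesis side), class-specific oscillatory
channel patterns, movement-type-dependent left/right energy asymmetry
(unimanual >> bimanual-asymmetric > bimanual-symmetric), and variable
segment durations matching the published length statistics (ROM mean 1016,
sd 492; ADL mean 4229, sd 3072 time points; floor 240).

Each movement class has a deterministic template: per accelerometer/
gyroscope channel, a sum of 2-4 sinusoids whose frequencies and phases are
a fixed function of (class, channel).  Participant variability enters only
through amplitude/phase jitter, a speed factor and duration; stroke
participants additionally get amplitude/phase distortion on the
affected-side sensors and inflated durations.  The dominant side for
unimanual and bimanual-asymmetric movements is the right for non-disabled
and right-hemiparesis participants and the left for left-hemiparesis
participants (who are instructed to use the affected limb).  The realized
pre-noise side-energy ratio is scaled to the movement type's target
exactly, so ln(ratio) sets the expected asymmetry score.

Magnetometer channels carry only a slowly varying offset plus noise; they
are discarded by preprocessing anyway.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_juimu import (
    Dataset,
    Recording,
    Segment,
    write_annotations,
    write_recording,
)
from .layout import (
    LEFT_SENSORS,
    RAW_LAYOUT,
    RIGHT_SENSORS,
    SENSOR_IDS,
    SENSOR_SWAP,
    Channel,
)

_TEMPLATE_ROOT = 7771  # root entropy for class templates; never varies
_STYLE_TAG = 101
_SEGMENT_TAG = 202

#: task defaults for segment-length statistics (time points)
LENGTH_STATS = {"ROM": (1016.0, 492.0), "ADL": (4229.0, 3072.0)}
DEFAULT_N_CLASSES = {"ROM": 14, "ADL": 56}

#: target right/left (dominant/non-dominant) energy ratios per movement
#: type; ln(ratio) matches the published absolute asymmetry scores
#: (UNI ~4.7, BIA ~0.51, BIS ~0.22)
DEFAULT_ASYM_RATIO = {"UNI": 110.0, "BIA": 1.67, "BIS": 1.25}


def default_class_type_map(task: str, n_classes: int) -> dict[int, str]:
    """ROM movements are all unimanual; ADL classes cycle UNI/BIA/BIS."""
    if task == "ROM":
        return {m: "UNI" for m in range(1, n_classes + 1)}
    cycle = ("UNI", "BIA", "BIS")
    return {m: cycle[(m - 1) % 3] for m in range(1, n_classes + 1)}


@dataclass(frozen=True)
class ParticipantMeta:
    """Identity, group, hemiparesis side and a stable seeding index."""

    participant_id: str
    group: str
    hemiparesis_side: str
    index: int


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the study-like conditions."""

    task: str = "ROM"
    n_nd: int = 3
    n_stroke: int = 2
    n_classes: int | None = None
    class_type_map: dict[int, str] | None = None
    length_mean: float | None = None
    length_sd: float | None = None
    length_floor: int = 240
    sample_rate: float = 80.0
    base_freq_range: tuple[float, float] = (0.5, 3.0)
    asym_energy_ratio: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASYM_RATIO)
    )
    # (amplitude jitter sd on log scale, phase jitter sd in radians,
    #  duration inflation factor) applied to stroke participants'
    # affected side (duration inflation affects the whole segment)
    stroke_distortion: tuple[float, float, float] = (0.3, 0.5, 1.3)
    # distortion attenuation for bimanual-symmetric movements: the affected
    # limb mirrors the intact limb's gross symmetric pattern, so its
    # execution is far less abnormal than when it carries the dominant or
    # delicate role (unimanual / bimanual-asymmetric movements)
    bis_distortion_scale: float = 0.3
    participant_amp_sd: float = 0.1
    participant_phase_sd: float = 0.2
    trunk_scale: float = 0.3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in LENGTH_STATS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_nd < 1 or self.n_stroke < 0:
            raise ValueError("participant counts must be >= 1 ND, >= 0 Stroke")
        if self.n_classes is None:
            self.n_classes = DEFAULT_N_CLASSES[self.task]
        if self.length_mean is None:
            self.length_mean = LENGTH_STATS[self.task][0]
        if self.length_sd is None:
            self.length_sd = LENGTH_STATS[self.task][1]
        if not self.length_sd < self.length_mean:
            raise ValueError("length_sd must be below length_mean")
        if self.class_type_map is None:
            self.class_type_map = default_class_type_map(self.task, self.n_classes)
        missing = [m for m in range(1, self.n_classes + 1)
                   if m not in self.class_type_map]
        if missing:
            raise ValueError(f"class_type_map missing classes {missing}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_type_map" in raw and raw["class_type_map"] is not None:
            raw["class_type_map"] = {int(k): v for k, v in raw["class_type_map"].items()}
        for key in ("base_freq_range", "stroke_distortion"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """A generated dataset plus per-segment ground-truth parameters."""

    dataset: Dataset
    ground_truth: pd.DataFrame
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# templates

_ACC_GYRO_CHANNELS: list[Channel] = [
    (s, m, a) for s in SENSOR_IDS for m in ("acc", "gyro") for a in ("x", "y", "z")
]


def _class_template_params(
    movement_id: int, base_freq_range: tuple[float, float]
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Deterministic (freqs, phases, amps) per acc/gyro channel for a class.

    Mirrored sensor pairs (right/left wrist, right/left upper arm) share
    one template per (modality, axis): performing a movement with the other
    limb mirrors the waveform onto the mirrored sensors, which is what
    makes the preprocessing side swap able to align left- and
    right-dominant executions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_TEMPLATE_ROOT, movement_id]))
    canonical: dict[Channel, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    params = []
    for sensor, modality, axis in _ACC_GYRO_CHANNELS:
        key = (min(sensor, SENSOR_SWAP[sensor]), modality, axis)
        if key not in canonical:
            k = int(rng.integers(2, 5))  # 2..4 sinusoids
            freqs = rng.uniform(*base_freq_range, size=k)
            phases = rng.uniform(0.0, 2.0 * math.pi, size=k)
            amps = rng.uniform(0.5, 1.5, size=k)
            amps = amps / math.sqrt(float(np.sum(amps**2) / 2.0))  # unit RMS
            canonical[key] = (freqs, phases, amps)
        params.append(canonical[key])
    return params


def _participant_style(
    spec: SyntheticSpec, participant: ParticipantMeta
) -> tuple[np.ndarray, float]:
    """Per-participant channel amplitude factors and a global speed factor."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, participant.index, _STYLE_TAG])
    )
    amp = np.exp(rng.normal(0.0, spec.participant_amp_sd, size=len(_ACC_GYRO_CHANNELS)))
    speed = float(np.exp(rng.normal(0.0, 0.03)))
    return amp, speed


def _dominant_side(participant: ParticipantMeta) -> str:
    return "left" if participant.hemiparesis_side == "left" else "right"


# ---------------------------------------------------------------------------
# generation


def generate_segment(
    spec: SyntheticSpec,
    participant: ParticipantMeta,
    movement_id: int,
) -> tuple[Segment, dict]:
    """Generate one [length x 45] segment and its ground-truth record.

    Deterministic: the per-segment random stream is derived from
    (spec.seed, participant.index, movement_id), so repeated calls with the
    same arguments return identical matrices.
    """
    if movement_id not in spec.class_type_map:
        raise KeyError(f"movement {movement_id} not in class_type_map")
    mtype = spec.class_type_map[movement_id]
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, participant.index, movement_id, _SEGMENT_TAG])
    )
    amp_style, speed = _participant_style(spec, participant)
    template = _class_template_params(movement_id, spec.base_freq_range)

    is_stroke = participant.group == "Stroke"
    amp_jitter_sd, phase_jitter_sd, duration_inflation = spec.stroke_distortion
    if mtype == "BIS":
        amp_jitter_sd *= spec.bis_distortion_scale
        phase_jitter_sd *= spec.bis_distortion_scale
    mean = spec.length_mean * (duration_inflation if is_stroke else 1.0)
    length = int(max(spec.length_floor, round(rng.normal(mean, spec.length_sd))))
    t = np.arange(length) / spec.sample_rate

    affected = participant.hemiparesis_side if is_stroke else "none"
    acc_gyro = np.empty((length, len(_ACC_GYRO_CHANNELS)))
    for ci, (sensor, _, _) in enumerate(_ACC_GYRO_CHANNELS):
        freqs, phases, amps = template[ci]
        phase_off = rng.normal(0.0, spec.participant_phase_sd, size=len(freqs))
        on_affected = (
            (affected == "right" and sensor in RIGHT_SENSORS)
            or (affected == "left" and sensor in LEFT_SENSORS)
        )
        if on_affected:
            phase_off = phase_off + rng.normal(0.0, phase_jitter_sd, size=len(freqs))
        x = np.zeros(length)
        for k in range(len(freqs)):
            x += amps[k] * np.sin(
                2.0 * math.pi * freqs[k] * speed * t + phases[k] + phase_off[k]
            )
        if sensor == 3:
            x *= spec.trunk_scale
        acc_gyro[:, ci] = x * amp_style[ci]

    # scale the non-dominant side so the realized pre-noise energy ratio
    # (dominant/non-dominant) equals the movement type's target exactly
    right_cols = [i for i, (s, _, _) in enumerate(_ACC_GYRO_CHANNELS) if s in RIGHT_SENSORS]
    left_cols = [i for i, (s, _, _) in enumerate(_ACC_GYRO_CHANNELS) if s in LEFT_SENSORS]
    centered = acc_gyro - acc_gyro.mean(axis=0, keepdims=True)
    er0 = float((centered[:, right_cols] ** 2).mean())
    el0 = float((centered[:, left_cols] ** 2).mean())
    ratio = float(spec.asym_energy_ratio[mtype])
    dominant = _dominant_side(participant)
    if dominant == "right":
        acc_gyro[:, left_cols] *= math.sqrt(er0 / (el0 * ratio))
        er_true, el_true = er0, er0 / ratio
    else:
        acc_gyro[:, right_cols] *= math.sqrt(el0 / (er0 * ratio))
        er_true, el_true = el0 / ratio, el0

    # stroke amplitude distortion on the affected side (after ratio scaling,
    # so realized asymmetry scatters around ln(ratio) as in real patients)
    if is_stroke and affected in ("left", "right"):
        side_sensors = RIGHT_SENSORS if affected == "right" else LEFT_SENSORS
        for ci, (sensor, _, _) in enumerate(_ACC_GYRO_CHANNELS):
            if sensor in side_sensors:
                acc_gyro[:, ci] *= math.exp(rng.normal(0.0, amp_jitter_sd))

    acc_gyro += rng.normal(0.0, spec.noise_sd, size=acc_gyro.shape)

    # assemble the full 45-channel matrix in raw layout order
    values = np.empty((length, RAW_LAYOUT.n_channels))
    acc_gyro_pos = {ch: i for i, ch in enumerate(_ACC_GYRO_CHANNELS)}
    for col, ch in enumerate(RAW_LAYOUT.channels()):
        if ch in acc_gyro_pos:
            values[:, col] = acc_gyro[:, acc_gyro_pos[ch]]
        else:  # magnetometer: slow drift + offset + mild noise
            f_slow = rng.uniform(0.02, 0.1)
            offset = rng.normal(0.0, 10.0)
            amp = rng.uniform(0.5, 2.0)
            values[:, col] = (
                offset
                + amp * np.sin(2.0 * math.pi * f_slow * t + rng.uniform(0, 2 * math.pi))
                + rng.normal(0.0, spec.noise_sd * 0.5, size=length)
            )

    segment = Segment(
        participant_id=participant.participant_id,
        group=participant.group,
        hemiparesis_side=participant.hemiparesis_side,
        task=spec.task,
        movement_id=movement_id,
        movement_type=mtype,
        values=values,
        channels=RAW_LAYOUT.channels(),
    )
    truth = {
        "participant_id": participant.participant_id,
        "movement_id": movement_id,
        "movement_type": mtype,
        "template_id": movement_id,
        "length": length,
        "dominant_side": dominant,
        "er_true": er_true,
        "el_true": el_true,
        "target_ratio": ratio,
    }
    return segment, truth


def make_participants(spec: SyntheticSpec) -> list[ParticipantMeta]:
    """ND participants, then stroke participants with alternating
    right/left hemiparesis sides."""
    out = [
        ParticipantMeta(f"ND{i + 1}", "ND", "none", i) for i in range(spec.n_nd)
    ]
    for j in range(spec.n_stroke):
        side = "right" if j % 2 == 0 else "left"
        out.append(
            ParticipantMeta(f"Stroke{j + 1}", "Stroke", side, spec.n_nd + j)
        )
    return out


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """One segment per (participant, class); reproducible from spec.seed."""
    segments: list[Segment] = []
    truths: list[dict] = []
    for participant in make_participants(spec):
        for movement_id in range(1, spec.n_classes + 1):
            seg, truth = generate_segment(spec, participant, movement_id)
            segments.append(seg)
            truths.append(truth)
    return SyntheticDataset(
        dataset=Dataset(segments=segments),
        ground_truth=pd.DataFrame(truths),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# writing the CSV dialect


def to_recordings(synth: SyntheticDataset) -> tuple[list[Recording], pd.DataFrame]:
    """Concatenate each participant's segments into one recording and build
    the matching annotation table (sample-index based, half-open)."""
    recordings: list[Recording] = []
    ann_rows: list[dict] = []
    by_pid: dict[str, list[Segment]] = {}
    for seg in synth.dataset.segments:
        by_pid.setdefault(seg.participant_id, []).append(seg)
    for pid, segs in by_pid.items():
        blocks = []
        cursor = 0
        for seg in segs:
            ann_rows.append(
                {
                    "participant_id": pid,
                    "group": seg.group,
                    "hemiparesis_side": seg.hemiparesis_side,
                    "task": seg.task,
                    "movement_id": seg.movement_id,
                    "movement_type": seg.movement_type,
                    "start_index": cursor,
                    "end_index": cursor + len(seg),
                }
            )
            blocks.append(seg.values)
            cursor += len(seg)
        values = np.vstack(blocks)
        timestamps = np.arange(len(values)) / synth.spec.sample_rate
        first = segs[0]
        recordings.append(
            Recording(
                participant_id=pid,
                group=first.group,
                hemiparesis_side=first.hemiparesis_side,
                task=first.task,
                timestamps=timestamps,
                values=values,
            )
        )
    return recordings, pd.DataFrame(ann_rows)


def write_dataset(synth: SyntheticDataset, out_dir: str | os.PathLike) -> None:
    """Write recordings (one CSV per participant), the annotation table and
    the ground-truth sidecar in the package's CSV dialect."""
    os.makedirs(out_dir, exist_ok=True)
    recordings, annotations = to_recordings(synth)
    for rec in recordings:
        write_recording(
            os.path.join(out_dir, f"{rec.participant_id}_{rec.task}.csv"), rec
        )
    write_annotations(os.path.join(out_dir, "annotations.csv"), annotations)
    synth.ground_truth.to_csv(
        os.path.join(out_dir, "ground_truth.csv"), index=False
    )
    with open(os.path.join(out_dir, "spec.yaml"), "w") as fh:
        spec_dict = asdict(synth.spec)
        spec_dict["asym_energy_ratio"] = dict(spec_dict["asym_energy_ratio"])
        yaml.safe_dump(spec_dict, fh)
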