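"""Segment preprocessing: centering, channel selection, side swap, linear
interpolation to a fixed length, and sliding windows.

The pipeline order is fixed: zero-center each channel over the segment,
keep the accelerometer + gyroscope channels (magnetometer readings depend
on the participant's heading relative to the Earth's field and are
dropped), swap left/right sensor blocks for left-hemiparesis participants
so the dominant activity sits on the same sensors for everyone, linearly
interpolate every segment to the task's fixed length, then cut fixed-count
sliding windows.  Because interpolation equalizes lengths first, every
segment yields the same number of windows — the window counts per class are
balanced by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_juimu import Dataset, Segment
from .layout import (
    AXES,
    SENSOR_IDS,
    SENSOR_SWAP,
    Channel,
    acc_gyro_subset,
    subset_channels,
)


def window_count(length: int, window_size: int, stride: int) -> int:
    """Number of sliding windows: advance by ``stride`` until the remainder
    is shorter than the window."""
    if window_size > length:
        raise ValueError("window_size exceeds segment length")
    return (length - window_size) // stride + 1


@dataclass(frozen=True)
class PreprocessConfig:
    """Task-level preprocessing parameters.

    Defaults must satisfy ``floor((target_length - window_size)/stride) + 1
    == windows_per_segment``; both task presets produce exactly 20 windows
    per segment.
    """

    target_length: int
    window_size: int
    stride: int
    windows_per_segment: int = 20
    channel_subset: tuple[tuple[int, str], ...] = tuple(acc_gyro_subset())
    swap_sides_for_left_hemiparesis: bool = True

    def __post_init__(self) -> None:
        if not self.channel_subset:
            raise ValueError("channel_subset must be nonempty")
        if self.window_size > self.target_length:
            raise ValueError("window_size exceeds target_length")
        n = window_count(self.target_length, self.window_size, self.stride)
        if n != self.windows_per_segment:
            raise ValueError(
                f"target_length/window_size/stride yield {n} windows, "
                f"expected {self.windows_per_segment}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_subset) * len(AXES)


#: ROM task preset: 1000 time points, 200-sample windows, stride 42 -> 20 windows
ROM_CONFIG = PreprocessConfig(target_length=1000, window_size=200, stride=42)
#: ADL task preset: 3700 time points, 740-sample windows, stride 150 -> 20 windows
ADL_CONFIG = PreprocessConfig(target_length=3700, window_size=740, stride=150)

TASK_CONFIGS = {"ROM": ROM_CONFIG, "ADL": ADL_CONFIG}


@dataclass
class Window:
    """A fixed-length [time x channel] slab, the classifier's input unit."""

    values: np.ndarray  # (window_size, n_channels)
    participant_id: str
    group: str
    task: str
    movement_id: int
    movement_type: str
    window_index: int
    segment_key: tuple  # (participant_id, movement_id, copy tag)


def zero_center(segment: Segment) -> Segment:
    """Subtract each channel's segment mean so all channel means are zero."""
    if len(segment) == 0:
        raise ValueError("empty segment")
    v = segment.values
    return segment.with_values(v - v.mean(axis=0, keepdims=True))


def select_channels(
    segment: Segment, subset: Sequence[tuple[int, str]]
) -> Segment:
    """Keep the channels of the given (sensor, modality) pairs, in
    (sensor, modality, axis) order.  The 5-sensor acc+gyro default yields
    the 30-channel model input; single-sensor subsets give the ablation
    inputs."""
    wanted = subset_channels(subset)
    pos = {ch: i for i, ch in enumerate(segment.channels)}
    try:
        cols = [pos[ch] for ch in wanted]
    except KeyError as exc:
        raise KeyError(f"channel {exc.args[0]!r} not present in segment") from exc
    return segment.with_values(segment.values[:, cols], channels=wanted)


def swap_sides(segment: Segment) -> Segment:
    """Exchange right/left sensor blocks (1<->2, 4<->5); trunk untouched.

    Only the sensor labels are exchanged — axis values are not negated.
    Applying the swap twice restores the original segment.
    """
    pos = {ch: i for i, ch in enumerate(segment.channels)}
    cols = []
    for (s, m, a) in segment.channels:
        partner = (SENSOR_SWAP[s], m, a)
        if partner not in pos:
            raise ValueError(
                f"cannot swap sides: channel {partner!r} missing from layout"
            )
        cols.append(pos[partner])
    return segment.with_values(segment.values[:, cols])


def interpolate_segment(segment: Segment, target_length: int) -> Segment:
    """Piecewise-linear resampling to exactly ``target_length`` rows.

    Query positions are ``target_length`` equally spaced points over the
    sample-index range [0, len-1]; endpoints are preserved exactly.  The
    abscissa is sample index, not wall-clock time.
    """
    n = len(segment)
    if n < 2:
        raise ValueError("cannot interpolate a segment shorter than 2 samples")
    x_old = np.arange(n, dtype=float)
    x_new = np.linspace(0.0, n - 1.0, target_length)
    out = np.empty((target_length, segment.values.shape[1]))
    for c in range(segment.values.shape[1]):
        out[:, c] = np.interp(x_new, x_old, segment.values[:, c])
    return segment.with_values(out)


def slide_windows(segment: Segment, config: PreprocessConfig) -> list[Window]:
    """Cut fixed-size windows at multiples of the stride.

    Requires the segment to be at the config's target length, so every
    segment yields exactly ``windows_per_segment`` windows; trailing rows
    not covered by the final window are discarded.
    """
    if len(segment) != config.target_length:
        raise ValueError(
            f"segment length {len(segment)} != target_length "
            f"{config.target_length}; interpolate first"
        )
    n = window_count(len(segment), config.window_size, config.stride)
    copy_tag = segment.provenance.get("copy", "orig")
    return [
        Window(
            values=segment.values[i * config.stride : i * config.stride + config.window_size],
            participant_id=segment.participant_id,
            group=segment.group,
            task=segment.task,
            movement_id=segment.movement_id,
            movement_type=segment.movement_type,
            window_index=i,
            segment_key=(segment.participant_id, segment.movement_id, copy_tag),
        )
        for i in range(n)
    ]


def preprocess_segment(segment: Segment, config: PreprocessConfig) -> Segment:
    """Center, select channels, swap sides if needed, and interpolate.

    Returns the fixed-length segment ready for windowing (augmentation, when
    enabled, rotates these fixed-length segments before windows are cut).
    """
    seg = zero_center(segment)
    seg = select_channels(seg, config.channel_subset)
    if config.swap_sides_for_left_hemiparesis and segment.hemiparesis_side == "left":
        seg = swap_sides(seg)
    return interpolate_segment(seg, config.target_length)


def preprocess_dataset(
    dataset: Dataset, config: PreprocessConfig
) -> tuple[list[Window], list[Segment]]:
    """Run the full pipeline over a dataset.

    Returns the window list plus the interpolated segments (the provenance
    trail: one fixed-length segment per input segment, in input order).
    """
    processed = [preprocess_segment(s, config) for s in dataset.segments]
    windows: list[Window] = []
    for seg in processed:
        windows.extend(slide_windows(seg, config))
    return windows, processed


def stack_windows(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (X, y) arrays for the classifier.

    X has shape (n_windows, window_size, n_channels); y holds movement ids.
    """
    X = np.stack([w.values for w in windows]).astype(np.float32)
    y = np.array([w.movement_id for w in windows], dtype=np.int64)
    return X, y
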