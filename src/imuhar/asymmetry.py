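"""Side-energy asymmetry score of a movement segment.

For zero-centered channel values x_{c,t}, the right- and left-side energies
are the mean per-channel mean square over the lateralized sensors:

    E_R = (1/N_R) * sum_{c in RC} (1/T) * sum_t x_{c,t}^2

and analogously E_L over LC, where RC/LC are the accelerometer + gyroscope
channels of the right (sensors 1, 4) and left (sensors 2, 5) wrist and
upper-arm sensors and T is the segment length.  The asymmetry score is the
stabilized natural-log energy ratio

    S_asym = ln((E_R + eps) / (E_L + eps)),   eps = 0.001

positive when the right side carries more energy, negative when the left
does, and zero at equality.  Its absolute value (AAS) quantifies the degree
of asymmetry irrespective of side: unimanual movements score highest,
bimanual-asymmetric ones intermediate, bimanual-symmetric ones lowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_juimu import Dataset, Segment
from .layout import LEFT_SENSORS, RIGHT_SENSORS, Channel
from .preprocessing import zero_center

EPSILON = 0.001

_LATERAL_MODALITIES = ("acc", "gyro")


@dataclass(frozen=True)
class SideChannelSets:
    """Indices of the right- and left-side channels within a segment."""

    right: tuple[int, ...]
    left: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.right) & set(self.left):
            raise ValueError("right and left channel sets overlap")
        if not self.right or not self.left:
            raise ValueError("empty side channel set")

    @classmethod
    def from_channels(cls, channels: list[Channel]) -> "SideChannelSets":
        """Locate the lateralized acc+gyro channels in a channel list.

        Under the default 30-channel layout each side has 12 channels
        (2 sensors x 2 modalities x 3 axes); trunk channels belong to
        neither side, magnetometer channels are never included.
        """
        right = tuple(
            i for i, (s, m, _) in enumerate(channels)
            if s in RIGHT_SENSORS and m in _LATERAL_MODALITIES
        )
        left = tuple(
            i for i, (s, m, _) in enumerate(channels)
            if s in LEFT_SENSORS and m in _LATERAL_MODALITIES
        )
        return cls(right=right, left=left)


@dataclass
class AsymmetryResult:
    """Per-segment energies and asymmetry score."""

    er: float
    el: float
    s_asym: float
    abs_s_asym: float
    epsilon: float = EPSILON


def side_energies(
    segment: Segment, sides: SideChannelSets | None = None
) -> tuple[float, float]:
    """Mean per-channel mean-square energy of the right and left sides.

    The segment is expected to be zero-centered (the score is defined on
    zero-averaged values).
    """
    if sides is None:
        sides = SideChannelSets.from_channels(segment.channels)
    v = segment.values
    sq = v * v
    er = float(sq[:, list(sides.right)].mean())
    el = float(sq[:, list(sides.left)].mean())
    return er, el


def asymmetry_score(er: float, el: float, epsilon: float = EPSILON) -> float:
    """Stabilized log energy ratio ln((E_R + eps)/(E_L + eps))."""
    if er < 0 or el < 0:
        raise ValueError("energies must be nonnegative")
    return float(np.log((er + epsilon) / (el + epsilon)))


def segment_asymmetry(
    segment: Segment,
    sides: SideChannelSets | None = None,
    epsilon: float = EPSILON,
    center: bool = True,
) -> AsymmetryResult:
    """Compute the full asymmetry result for one segment.

    ``center=True`` (default) zero-centers first so raw segments can be
    scored directly; pass ``center=False`` for already-centered data.
    """
    seg = zero_center(segment) if center else segment
    er, el = side_energies(seg, sides)
    s = asymmetry_score(er, el, epsilon)
    return AsymmetryResult(er=er, el=el, s_asym=s, abs_s_asym=abs(s), epsilon=epsilon)


def asymmetry_table(dataset: Dataset, epsilon: float = EPSILON) -> pd.DataFrame:
    """Per-segment scores for a whole dataset (one row per segment)."""
    rows = []
    for seg in dataset.segments:
        res = segment_asymmetry(seg, epsilon=epsilon)
        rows.append(
            {
                "participant_id": seg.participant_id,
                "group": seg.group,
                "task": seg.task,
                "movement_id": seg.movement_id,
                "movement_type": seg.movement_type,
                "er": res.er,
                "el": res.el,
                "s_asym": res.s_asym,
                "abs_s_asym": res.abs_s_asym,
            }
        )
    return pd.DataFrame(rows)


def aas_by_movement_type(
    dataset: Dataset, epsilon: float = EPSILON, pooled: bool = False
) -> pd.DataFrame:
    """Mean +/- sd of the absolute asymmetry score per movement type.

    Default aggregation averages |S_asym| per movement across participants
    first, then summarizes movements within each type (mean and sd over
    movement means); ``pooled=True`` instead pools all segments of a type.
    Types with no segments are omitted.  A single-movement (or
    single-segment) group reports sd 0.
    """
    table = asymmetry_table(dataset, epsilon=epsilon)
    if table.empty:
        return pd.DataFrame(columns=["movement_type", "mean_aas", "sd_aas", "n"])
    if pooled:
        grouped = table.groupby("movement_type")["abs_s_asym"]
        out = grouped.agg(mean_aas="mean", sd_aas=lambda v: float(np.std(v, ddof=0)),
                          n="count")
    else:
        per_movement = (
            table.groupby(["movement_type", "movement_id"])["abs_s_asym"]
            .mean()
            .reset_index()
        )
        grouped = per_movement.groupby("movement_type")["abs_s_asym"]
        out = grouped.agg(mean_aas="mean", sd_aas=lambda v: float(np.std(v, ddof=0)),
                          n="count")
    return out.reset_index()
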