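"""Axis-rotation data augmentation.

Each sensor's accelerometer (and gyroscope) sample is a 3-vector; rotating
those vectors by a random angle about a random 3-D axis simulates the
variability in how hands and arms are oriented during a movement.  Angles
are drawn uniformly from (-90, +90) degrees and axes uniformly on the unit
sphere.  Augmentation doubles the training set: the original segments plus
one rotated copy of each.  It is applied to training data only, at the
segment level, so all windows cut from one augmented segment share a single
rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_juimu import Segment


@dataclass(frozen=True)
class RotationSpec:
    """Sampling spec for random rotations.

    ``scope`` controls whether one rotation is shared by every sensor
    triplet of a segment (``per_segment_global``, the default — a
    whole-recording orientation change) or drawn independently per sensor
    (``per_sensor``).
    """

    angle_range: tuple[float, float] = (-90.0, 90.0)
    scope: str = "per_segment_global"

    def __post_init__(self) -> None:
        lo, hi = self.angle_range
        if not lo < hi:
            raise ValueError("empty angle range")
        if self.scope not in ("per_segment_global", "per_sensor"):
            raise ValueError(f"unknown scope {self.scope!r}")


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be nonzero")
    u = axis / norm
    theta = math.radians(angle_deg)
    k = np.array(
        [[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]]
    )
    return np.eye(3) + math.sin(theta) * k + (1.0 - math.cos(theta)) * (k @ k)


def draw_rotation(
    rng: np.random.Generator, angle_range: tuple[float, float] = (-90.0, 90.0)
) -> tuple[np.ndarray, float]:
    """Draw a uniform axis (on the sphere) and a uniform angle in degrees."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            break
    angle = float(rng.uniform(*angle_range))
    return v / n, angle


def _triplet_starts(segment: Segment) -> list[int]:
    """Start columns of consecutive (sensor, modality) x/y/z triplets."""
    ch = segment.channels
    if len(ch) % 3 != 0:
        raise ValueError("channel count not divisible into xyz triplets")
    starts = []
    for i in range(0, len(ch), 3):
        (s0, m0, a0), (s1, m1, a1), (s2, m2, a2) = ch[i : i + 3]
        if not (s0 == s1 == s2 and m0 == m1 == m2 and (a0, a1, a2) == ("x", "y", "z")):
            raise ValueError(f"columns {i}..{i+2} do not form an xyz triplet")
        starts.append(i)
    return starts


def rotate_segment(
    segment: Segment,
    spec: RotationSpec,
    rng: np.random.Generator,
) -> Segment:
    """Return a rotated copy of the segment (metadata and labels unchanged).

    Accelerometer and gyroscope triplets transform identically — both are
    vectors under a frame rotation.  The drawn axis/angle are recorded in
    the copy's provenance.
    """
    starts = _triplet_starts(segment)
    out = segment.values.copy()
    if spec.scope == "per_segment_global":
        axis, angle = draw_rotation(rng, spec.angle_range)
        rots = {i: (axis, angle) for i in starts}
    else:
        per_sensor: dict[int, tuple[np.ndarray, float]] = {}
        for i in starts:
            sensor = segment.channels[i][0]
            if sensor not in per_sensor:
                per_sensor[sensor] = draw_rotation(rng, spec.angle_range)
        rots = {i: per_sensor[segment.channels[i][0]] for i in starts}
    prov_rots = []
    for i in starts:
        axis, angle = rots[i]
        r = rotation_matrix(axis, angle)
        out[:, i : i + 3] = segment.values[:, i : i + 3] @ r.T
        prov_rots.append((tuple(float(x) for x in axis), angle))
    return segment.with_values(
        out, copy="rotated", rotation=prov_rots[0] if spec.scope == "per_segment_global" else prov_rots
    )


def augment_segments(
    segments: Sequence[Segment],
    spec: RotationSpec,
    rng: np.random.Generator,
) -> list[Segment]:
    """Original segments plus one independently rotated copy of each.

    Output size is exactly twice the input; the class label distribution of
    the rotated half equals that of the originals.  Training-set use only —
    evaluation data is never augmented.
    """
    rotated = [rotate_segment(s, spec, rng) for s in segments]
    return list(segments) + rotated
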