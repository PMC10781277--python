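"""Channel layout of the five-IMU recording setup.

Five sensors are worn at fixed body locations: sensor 1 on the right wrist,
2 on the left wrist, 3 on the trunk, 4 on the right upper arm and 5 on the
left upper arm.  Each sensor reports accelerometer, gyroscope and
magnetometer readings along x, y and z, giving 5 x 3 x 3 = 45 raw channels
per sample.  The raw CSV column order is (sensor 1..5) x (acc, gyro, mag)
x (x, y, z); every module in this package identifies a channel by its
(sensor, modality, axis) tuple and relies on this module for the bijection
between tuples and column indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

SENSOR_IDS: tuple[int, ...] = (1, 2, 3, 4, 5)
MODALITIES: tuple[str, ...] = ("acc", "gyro", "mag")
AXES: tuple[str, ...] = ("x", "y", "z")

#: body side of each sensor; the trunk sensor is unlateralized
SENSOR_SIDE: dict[int, str] = {1: "right", 2: "left", 3: "trunk", 4: "right", 5: "left"}

#: left/right partner of each sensor (trunk maps to itself)
SENSOR_SWAP: dict[int, int] = {1: 2, 2: 1, 3: 3, 4: 5, 5: 4}

#: right- and left-side sensor ids (wrist + upper arm)
RIGHT_SENSORS: tuple[int, ...] = (1, 4)
LEFT_SENSORS: tuple[int, ...] = (2, 5)

Channel = tuple[int, str, str]  # (sensor id, modality, axis)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered mapping between channel tuples and column indices."""

    sensor_ids: tuple[int, ...] = SENSOR_IDS
    modalities: tuple[str, ...] = MODALITIES
    axes: tuple[str, ...] = AXES

    @property
    def n_channels(self) -> int:
        return len(self.sensor_ids) * len(self.modalities) * len(self.axes)

    def channels(self) -> list[Channel]:
        """All channel tuples in column order."""
        return [
            (s, m, a)
            for s in self.sensor_ids
            for m in self.modalities
            for a in self.axes
        ]

    def index(self, channel: Channel) -> int:
        """Column index of a (sensor, modality, axis) tuple."""
        s, m, a = channel
        try:
            return (
                self.sensor_ids.index(s) * len(self.modalities) * len(self.axes)
                + self.modalities.index(m) * len(self.axes)
                + self.axes.index(a)
            )
        except ValueError as exc:
            raise KeyError(f"unknown channel {channel!r}") from exc

    def tuple_of(self, index: int) -> Channel:
        """Inverse of :meth:`index`."""
        if not 0 <= index < self.n_channels:
            raise IndexError(index)
        per_sensor = len(self.modalities) * len(self.axes)
        s, rem = divmod(index, per_sensor)
        m, a = divmod(rem, len(self.axes))
        return (self.sensor_ids[s], self.modalities[m], self.axes[a])

    def column_names(self) -> list[str]:
        return [f"s{s}_{m}_{a}" for s, m, a in self.channels()]


RAW_LAYOUT = ChannelLayout()


def acc_gyro_subset(sensors: Iterable[int] = SENSOR_IDS) -> list[tuple[int, str]]:
    """(sensor, modality) pairs selecting accelerometer + gyroscope channels.

    The default over all five sensors is the 30-channel model input; passing
    ``sensors=(1,)`` gives the single right-wrist subset used in ablations.
    """
    return [(s, m) for s in sensors for m in ("acc", "gyro")]


def subset_channels(
    subset: Sequence[tuple[int, str]], axes: Sequence[str] = AXES
) -> list[Channel]:
    """Expand (sensor, modality) pairs into ordered channel tuples."""
    for s, m in subset:
        if s not in SENSOR_IDS:
            raise KeyError(f"unknown sensor {s!r}")
        if m not in MODALITIES:
            raise KeyError(f"unknown modality {m!r}")
    return [(s, m, a) for s, m in subset for a in axes]
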