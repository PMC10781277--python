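import numpy as np
import pytest

from imuhar.io_juimu import Segment
from imuhar.layout import RAW_LAYOUT
from imuhar.synthetic import SyntheticSpec, generate_dataset


def make_segment(values: np.ndarray, *, hemiparesis_side: str = "none",
                 group: str = "ND", movement_id: int = 1,
                 movement_type: str = "UNI", channels=None,
                 participant_id: str = "ND1") -> Segment:
    """Wrap a raw value matrix in a Segment with minimal metadata."""
    return Segment(
        participant_id=participant_id,
        group=group,
        hemiparesis_side=hemiparesis_side,
        task="ROM",
        movement_id=movement_id,
        movement_type=movement_type,
        values=values,
        channels=list(channels) if channels is not None else RAW_LAYOUT.channels(),
    )


@pytest.fixture(scope="session")
def small_rom_dataset():
    """4 participants (2 ND + 2 stroke, one per side) x 4 classes, short
    segments: the shared small fixture for pipeline tests."""
    spec = SyntheticSpec(
        task="ROM", n_nd=2, n_stroke=2, n_classes=4,
        length_mean=300.0, length_sd=60.0, length_floor=120, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
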