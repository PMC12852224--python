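import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from fsukin.frames import build_mount_frames
from fsukin.synthetic import (
    FsuGeneratorParams,
    ShiftSpec,
    apply_synthetic_shift,
    generate_fsu,
)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return ScipyRotation.random(rng=rng).as_matrix()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def symmetric_fsu():
    """Axis-aligned, left-right symmetric two-level fixture."""
    return generate_fsu(FsuGeneratorParams())


@pytest.fixture
def skewed_fsu():
    """Asymmetric, skewed fixture resembling a scoliotic segment."""
    return generate_fsu(
        FsuGeneratorParams(
            caudal_skew_deg=(2.0, -3.0, 4.0),
            cranial_skew_deg=(5.0, 8.0, 10.0),
            asymmetry=0.15,
        )
    )


@pytest.fixture
def shifted_fsu(skewed_fsu):
    """Skewed fixture plus a rest-pose shift of intraoperative magnitude."""
    relative_io, truth = apply_synthetic_shift(
        skewed_fsu.reference, ShiftSpec(translation_mm=3.0, rotation_deg=20.0, seed=11)
    )
    return skewed_fsu, relative_io, truth


@pytest.fixture
def mounts(skewed_fsu):
    return build_mount_frames(
        skewed_fsu.caudal_entries,
        skewed_fsu.cranial_entries,
        skewed_fsu.reference.caudal,
        skewed_fsu.reference.cranial,
    )
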