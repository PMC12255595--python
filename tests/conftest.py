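import numpy as np
import pytest

from reconqc.synthetic_cohort import CohortConfig, generate_phantom_slice
from reconqc.types import Arm, ImageSlice


@pytest.fixture(scope="session")
def seeded_pairs():
    """Ten seeded random 8x8 nonnegative image pairs for oracle checks."""
    rng = np.random.default_rng(1234)
    return [
        (rng.uniform(0.0, 200.0, (8, 8)), rng.uniform(0.0, 200.0, (8, 8)))
        for _ in range(10)
    ]


@pytest.fixture(scope="session")
def seeded_pairs_16():
    rng = np.random.default_rng(4321)
    return [
        (rng.uniform(0.0, 200.0, (16, 16)), rng.uniform(0.0, 200.0, (16, 16)))
        for _ in range(10)
    ]


@pytest.fixture(scope="session")
def phantom():
    """One 128x128 clean phantom slice."""
    return generate_phantom_slice(7, size=128)


@pytest.fixture(scope="session")
def noisy_phantom(phantom):
    rng = np.random.default_rng(99)
    return np.sqrt(
        (phantom + rng.normal(0, 6.0, phantom.shape)) ** 2
        + rng.normal(0, 6.0, phantom.shape) ** 2
    )


@pytest.fixture
def tiny_config():
    """Small, fast cohort configuration for pipeline-level tests."""
    return CohortConfig(
        n_reference=6,
        n_constancy=3,
        n_perturbation_per_system=1,
        scanner_ids=("A", "B"),
        slices_min=3,
        slices_max=4,
        image_size=96,
        master_seed=11,
    )


def make_slices(positions, arm=Arm.AI, exam_id="e1", scanner_id="s1", value=1.0, size=4):
    """Helper: constant-valued slices at the given positions."""
    return [
        ImageSlice(
            pixels=np.full((size, size), value),
            slice_position_mm=float(p),
            exam_id=exam_id,
            scanner_id=scanner_id,
            arm=arm,
        )
        for p in positions
    ]
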