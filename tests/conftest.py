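import numpy as np
import pytest

from sgknee.phantom import PhantomParams, generate_exam
from sgknee.rng import substream
from sgknee.training import InMemoryDataset, LoadedExam
from sgknee.volume_io import ExamVolume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ramp_volume():
    """Deterministic 3x4x4 ramp stack."""
    data = np.arange(48, dtype=np.float32).reshape(3, 4, 4)
    return ExamVolume(data, view="axial", exam_id="ramp")


@pytest.fixture(scope="session")
def tiny_phantom_params():
    """Small, fast phantom population for unit tests (32 px, 8-10 slices)."""
    return PhantomParams(
        spatial_size=32, layer_range=(8, 10), band_width=3.0, gap_length=6.0,
        noise_sd=0.05, pos_fraction=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_phantom_params):
    """24 in-memory phantom exams, balanced classes."""
    exams = []
    for i in range(24):
        label = i % 2
        gen = substream(tiny_phantom_params.seed, f"tinyset/{i}")
        views = generate_exam(tiny_phantom_params, label, gen, exam_id=f"t{i:03d}")
        exams.append(LoadedExam(f"t{i:03d}", label, views))
    return InMemoryDataset(exams)


@pytest.fixture
def three_views(tiny_phantom_params):
    gen = substream(1, "three_views")
    return generate_exam(tiny_phantom_params, 0, gen, exam_id="tv")
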