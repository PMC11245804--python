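import numpy as np
import pytest

from radnet.fixtures import FixtureConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~200 records over all 5 modalities and body parts."""
    return generate_dataset(FixtureConfig(n_exams=80, files_per_exam_range=(1, 4),
                                          seed=42))


@pytest.fixture(scope="session")
def paired_dataset():
    """5 planted (modality x body part) groups, ~240 records."""
    return generate_dataset(FixtureConfig(n_exams=120,
                                          files_per_exam_range=(1, 3),
                                          paired_groups=True, seed=7))


@pytest.fixture(scope="session")
def blob_embeddings():
    """Three well-separated Gaussian blobs with labels."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(c, 0.15, size=(40, 6))
                   for c in ((0, 0, 0, 0, 0, 0), (4, 4, 0, 0, 0, 0),
                             (0, 0, 4, 4, 0, 0))])
    y = np.repeat(["a", "b", "c"], 40)
    return X, y
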