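"""Shared fixtures: small synthetic datasets and trained toy models.

Everything is generated at test time from seeds; expensive artefacts
(a trained teacher) are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from irmkd import (
    DistillationConfig,
    SyntheticLeafSpec,
    generate_dataset,
    train_teacher,
)

# frozen desk-scale study conditions used by the engine/evaluation/acceptance tests
STUDY_SPEC = SyntheticLeafSpec(
    n_classes=4, images_per_class=30, image_size=32, background="cluttered", seed=7
)
STUDY_CONFIG = DistillationConfig(
    n_classes=4,
    epochs=30,
    batch_size=32,
    image_size=32,
    seed=2,
    teacher_widths=(16, 32, 64),
    student_widths=(3, 6, 12),
)


def grad_check(f, x0: np.ndarray, analytic: np.ndarray, eps: float = 1e-6, atol: float = 1e-6):
    """Central-difference check of ``analytic`` = dF/dx at x0 for scalar F."""
    num = np.zeros_like(x0, dtype=float)
    flat_num = num.reshape(-1)
    flat_x = x0.reshape(-1)
    for i in range(flat_x.size):
        orig = flat_x[i]
        flat_x[i] = orig + eps
        fp = f(x0)
        flat_x[i] = orig - eps
        fm = f(x0)
        flat_x[i] = orig
        flat_num[i] = (fp - fm) / (2 * eps)
    np.testing.assert_allclose(analytic, num, rtol=1e-4, atol=atol)


@pytest.fixture(scope="session")
def study_dataset():
    batch, names = generate_dataset(STUDY_SPEC)
    return batch, names


@pytest.fixture(scope="session")
def trained_teacher(study_dataset):
    batch, _ = study_dataset
    model, log = train_teacher(STUDY_CONFIG, dataset=batch)
    return model, log


@pytest.fixture()
def tiny_batch():
    """A fast 3-class, 32 px batch for shape/plumbing tests."""
    spec = SyntheticLeafSpec(n_classes=3, images_per_class=4, image_size=32, seed=11)
    batch, _ = generate_dataset(spec)
    return batch
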