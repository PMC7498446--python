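import numpy as np
import pytest

import strokeatlas as sa


@pytest.fixture(scope="session")
def bundle():
    return sa.build_simplified_atlas(2.0)


@pytest.fixture(scope="session")
def symmetric_phantom():
    return sa.make_head_phantom(sa.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def lesion_phantom():
    return sa.make_head_phantom(sa.PhantomConfig(
        seed=12,
        lesion_specs=(sa.LesionSpec("left", (-40.0, -5.0, 5.0), 14.0, "hypodense"),),
    ))


def warp_with_truth(bundle, ph, **kw):
    """Individualize the atlas using the phantom's exact ground-truth landmarks."""
    warped, transform = sa.individualize_atlas(
        bundle, ph.volume, method="landmarks-given",
        landmarks=ph.truth_landmarks, frame_rot=ph.truth_frame,
        frame_origin=ph.truth_frame_origin, **kw,
    )
    return warped, transform


@pytest.fixture(scope="session")
def warped_symmetric(bundle, symmetric_phantom):
    return warp_with_truth(bundle, symmetric_phantom)[0]


@pytest.fixture(scope="session")
def warped_lesion(bundle, lesion_phantom):
    return warp_with_truth(bundle, lesion_phantom)[0]


@pytest.fixture(scope="session")
def small_cohort():
    return sa.make_cohort(sa.CohortSpec(n_cases=12, seed=3))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
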