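import numpy as np
import pytest

from lowfield import LesionSpec, PhantomSpec, build_phantom
from lowfield.image import VolumeImage, centered_affine


@pytest.fixture(scope="session")
def default_truth():
    """Full-size phantom with one 10 mm lesion, textured tissue."""
    spec = PhantomSpec(
        lesions=[
            LesionSpec(
                center=(25.5, -20.5, 10.5),
                semi_axes=(5.0, 5.0, 5.0),
                contrast={"FLAIR": 0.25, "T1w": -0.15},
            )
        ]
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def flat_truth():
    """Texture-free phantom (exactly piecewise-constant truth images)."""
    spec = PhantomSpec(
        texture_sd=0.0,
        lesions=[
            LesionSpec(
                center=(25.5, -20.5, 10.5),
                semi_axes=(5.0, 5.0, 5.0),
                contrast={"FLAIR": 0.25, "T1w": -0.15},
            )
        ],
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def small_truth():
    """Small, fast phantom for registration / reslicing tests."""
    spec = PhantomSpec(
        grid_shape=(64, 72, 60),
        brain_semi_axes=(26.0, 30.0, 24.0),
        rim_thickness_mm=4.0,
        ventricles=(((-6.0, 3.0, 4.0), (4.0, 10.0, 5.0)), ((6.0, 3.0, 4.0), (4.0, 10.0, 5.0))),
        lesions=[
            LesionSpec(center=(12.5, -10.5, 5.5), semi_axes=(4.0, 4.0, 4.0), contrast={"FLAIR": 0.25, "T1w": -0.15})
        ],
    )
    return build_phantom(spec)


def make_volume(data, spacing=(1.0, 1.0, 1.0), modality="FLAIR"):
    data = np.asarray(data, dtype=float)
    return VolumeImage(data, centered_affine(data.shape, spacing), modality=modality)


@pytest.fixture
def mk_volume():
    return make_volume
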