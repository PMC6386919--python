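import numpy as np
import pytest

from slvol import SceneSpec, build_calibration, render_calibration_stack

SESSION_DEPTHS = [20.0 + k for k in range(37)]  # 20..56 cm, 1 cm steps


@pytest.fixture(scope="session")
def clean_plane_spec():
    """Noise-free planar calibration scene."""
    return SceneSpec(surface="plane", gaussian_sigma=0.0, reflection_count=0,
                     seed=11)


@pytest.fixture(scope="session")
def clean_stack(clean_plane_spec):
    return render_calibration_stack(clean_plane_spec, SESSION_DEPTHS)


@pytest.fixture(scope="session")
def clean_frame_30(clean_plane_spec):
    """One noise-free planar frame at 30 cm with its ground truth."""
    stack = render_calibration_stack(clean_plane_spec, [30.0])
    return stack.images[0], stack.truth[0]


@pytest.fixture(scope="session")
def model(clean_stack):
    """Calibration model over 20-56 cm built from the noise-free stack."""
    return build_calibration(list(zip(clean_stack.images, clean_stack.depths_cm)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
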