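import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phospad as pp
from phospad.synthgen import SceneParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def field_layout():
    return pp.build_field_layout("0421")


@pytest.fixture(scope="session")
def scene_template():
    """Default capture conditions at a compact test scale (5 px/mm)."""
    return SceneParams(pixels_per_mm=5.0)


@pytest.fixture(scope="session")
def calibration_points(field_layout, scene_template):
    """Quantified standards 0-10 mg/L step 1, six replicate devices each."""
    dataset = pp.generate_calibration_set(
        range(11), 6, layout=field_layout, scene_template=scene_template, seed=1
    )
    return [
        (scene.concentration, pp.quantify_scene(r.image, field_layout, r.truth).ari_mean)
        for scene, r in dataset
    ]


@pytest.fixture(scope="session")
def fitted_model(calibration_points):
    return pp.fit_calibration(calibration_points)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
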