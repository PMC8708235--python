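import numpy as np
import pytest

from orthoskin.geometry import CameraCalib, RigidPose
from orthoskin.render import CameraView
from orthoskin.synthdata import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse markerless phantom shared by geometry-light tests."""
    return build_phantom(PhantomSpec(segments=64, rings_per_meter=36))


@pytest.fixture(scope="session")
def frontal_view():
    """Camera stop looking at the phantom from the front at 0.8 m radius."""
    return CameraView(
        pose=RigidPose.from_degrees(0.0, 1.0, 0.8),
        calib=CameraCalib.ideal(2.5e-4, (640, 480)),
        view_id=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
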