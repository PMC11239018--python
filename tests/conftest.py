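import numpy as np
import pytest

from trackscope.optics import OpticsConfig, OrganismModel, OrganismState, render_frame
from trackscope.stage import StageConfig, StageState


@pytest.fixture
def stage_cfg():
    return StageConfig()


@pytest.fixture
def optics():
    return OpticsConfig()


@pytest.fixture
def quiet_optics():
    """Noise-free bright-field scene for exact tracker checks."""
    return OpticsConfig(noise_sigma=0.0)


@pytest.fixture
def ellipse_model():
    return OrganismModel(kind="ballistic", speed_um_s=0.0, body_long_um=60.0, body_short_um=40.0)


@pytest.fixture
def render(quiet_optics, ellipse_model):
    """Render a noise-free frame with the organism at a given pixel offset
    from the frame centre (stage at the origin)."""

    def _render(dx_px=0.0, dy_px=0.0, heading=0.0, optics=None, model=None):
        opt = optics or quiet_optics
        mod = model or ellipse_model
        state = OrganismState(
            x_um=dx_px * opt.pixel_scale_um,
            y_um=dy_px * opt.pixel_scale_um,
            heading_rad=heading,
        )
        return render_frame(opt, mod, state, StageState()), state

    return _render


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
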