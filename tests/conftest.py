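import math

import numpy as np
import pytest

import golgimap as gm


@pytest.fixture
def noiseless_model():
    """Expectation-only imaging model (no Poisson, no read noise)."""
    return gm.ImagingModel(noise=False)


@pytest.fixture
def sharp_model():
    """No PSF, no noise: layer peaks land exactly on the geometry."""
    return gm.ImagingModel(psf_sigma_nm=0.0, noise=False)


@pytest.fixture
def default_geometry():
    """Vertical stack axis, no tilt, cis/tgn/poi at 0/400/550 nm."""
    return gm.StackGeometry(
        center_xy=None,
        axis_angle_inplane=math.pi / 2,
        tilt_outofplane=0.0,
        layer_offsets_nm=(0.0, 400.0, 550.0),
    )


def make_profile(values, step_px=0.5, pixel_size_nm=40.0):
    """Build an IntensityProfile directly from per-channel arrays
    (roles cis/tgn/poi map onto channels a/b/c)."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    n = len(next(iter(arrays.values())))
    t = np.arange(n) * step_px
    roles = dict(zip(("cis", "tgn", "poi"), arrays))
    roi = gm.LineROI("cell", "stack", (0.0, 0.0), ((n - 1) * step_px, 0.0),
                     width_px=1, sample_step_px=step_px)
    return gm.IntensityProfile(
        roi=roi,
        positions_px=t,
        positions_nm=t * pixel_size_nm,
        raw=arrays,
        channel_roles=roles,
        pixel_size_nm=pixel_size_nm,
    )


@pytest.fixture
def profile_factory():
    return make_profile
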