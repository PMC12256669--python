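import numpy as np
import pytest

import mlemlab as ml


@pytest.fixture(scope="session")
def geom64():
    """64-px grid, 3-degree step: the small reconstruction workhorse."""
    return ml.ProjectionGeometry.with_step(64, 3.0)


@pytest.fixture(scope="session")
def geom32():
    return ml.ProjectionGeometry.with_step(32, 6.0)


@pytest.fixture(scope="session")
def disk64(geom64):
    """Centered disk and its noiseless sinogram."""
    img = ml.make_disk(64, 24, 1.0, 0)
    return img, ml.forward_project(img, geom64)


@pytest.fixture(scope="session")
def cardiac96():
    """Small cardiac phantom pair (control, S/M = 4) on a 96^3 grid."""
    lesion = ml.SpotSpec(shape="sphere", intensity_ratio=4.0,
                         diameter_mm=30.0, reference="myocardium")
    ctrl = ml.make_cardiac_phantom(ml.CardiacPhantomSpec(matrix=(96, 96, 96)))
    hot = ml.make_cardiac_phantom(
        ml.CardiacPhantomSpec(matrix=(96, 96, 96), lesion=lesion))
    return ctrl, hot


@pytest.fixture(scope="session")
def annulus_slice():
    """Synthetic short-axis-like slice: a bright ring on a dim background."""
    N = 96
    ii, jj = np.indices((N, N))
    r = np.hypot(ii - (N - 1) / 2, jj - (N - 1) / 2)
    vals = np.where((r >= 12) & (r <= 18), 75.0, 0.5)
    return ml.Image2D(vals)
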