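import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def circle_boundary(center, radius, n=360):
    """Closed (y, x) polyline of a circle (image convention, y down)."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack(
        [center[0] - radius * np.sin(theta), center[1] + radius * np.cos(theta)], axis=1
    )


def ellipse_boundary(center, a, b, n=360):
    """Closed (y, x) polyline of an axis-aligned ellipse; semi-axis a along x."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = a * b / np.sqrt(b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)
    return np.stack([center[0] - r * np.sin(theta), center[1] + r * np.cos(theta)], axis=1)


@pytest.fixture
def smooth_image(rng):
    """A smooth, feature-rich test image (for registration tests)."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.random((96, 96)), 4.0)
    img -= img.min()
    return img * 100.0
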