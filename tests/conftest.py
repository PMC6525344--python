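import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from onlshape.onlb import Contour

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_ellipse(semi_major=100.0, semi_minor=60.0, theta_deg=0.0,
                 center=(256.0, 256.0), n=1024):
    """Parametric ellipse contour in image coordinates (y = row, downward).

    ``theta_deg`` is the major-axis angle in the fundus view (counter-
    clockwise positive), matching the package's reporting convention.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    th = np.radians(theta_deg)
    u = semi_major * np.cos(t)
    v = semi_minor * np.sin(t)
    x = center[0] + u * np.cos(th) - v * np.sin(th)
    y = center[1] - (u * np.sin(th) + v * np.cos(th))
    return Contour(np.column_stack([x, y]))


def make_rippled(radius=100.0, amp=0.2, lobes=12, center=(256.0, 256.0), n=2048):
    """Circle with a radial cosine ripple (crenellated boundary)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius * (1.0 + amp * np.cos(lobes * t))
    x = center[0] + r * np.cos(t)
    y = center[1] - r * np.sin(t)
    return Contour(np.column_stack([x, y]))


@pytest.fixture
def ellipse_2to1():
    return make_ellipse(semi_major=200.0, semi_minor=100.0)


@pytest.fixture
def circle():
    return make_ellipse(semi_major=100.0, semi_minor=100.0)
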