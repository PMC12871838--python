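import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def ellipse_points(params, n=200, arc=1.0, sigma=0.0, rng=None, t0=0.0):
    """Points on (an arc of) an ellipse, optionally jittered."""
    cx, cy, a, b, th = params
    t = t0 + np.linspace(0.0, 2.0 * np.pi * arc, n)
    ct, st = np.cos(th), np.sin(th)
    ex, ey = a * np.cos(t), b * np.sin(t)
    x = cx + ex * ct - ey * st
    y = cy + ex * st + ey * ct
    if sigma > 0:
        x = x + rng.normal(0, sigma, n)
        y = y + rng.normal(0, sigma, n)
    return np.column_stack([x, y])


def circle_arc(radius, span=np.pi, spacing=0.5, center=(0.0, 0.0)):
    """Contour points along a circular arc at fixed arc-length spacing."""
    n = max(int(radius * span / spacing), 8)
    t = np.linspace(0.0, span, n)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
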