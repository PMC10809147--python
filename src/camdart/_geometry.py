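"""Shared polar-coordinate conventions.

Pixel indices are 0-based ``(row, col) = (y, x)`` with pixel centers at
integer coordinates.  Polar angles are measured counterclockwise from the
+x (column) axis *as seen on screen*, i.e. image "up" (-y) is ``pi/2``.
All modules that convert between Cartesian and polar coordinates go
through these two helpers so the convention cannot drift.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def polar_from_cartesian(dy, dx):
    """(dy, dx) offsets -> (r, theta) with theta in [0, 2*pi)."""
    r = np.hypot(dy, dx)
    theta = np.arctan2(-np.asarray(dy, dtype=float), np.asarray(dx, dtype=float)) % TWO_PI
    return r, theta


def cartesian_from_polar(r, theta):
    """(r, theta) -> (dy, dx) offsets in image coordinates (y down)."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return -r * np.sin(theta), r * np.cos(theta)


def wrap_angle(theta):
    """Wrap angle(s) into [0, 2*pi)."""
    return np.asarray(theta, dtype=float) % TWO_PI


def angular_distance(a, b):
    """Smallest absolute angular separation between a and b."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % TWO_PI
    return np.minimum(d, TWO_PI - d)
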