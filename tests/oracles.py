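"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def closed_form_volume_ml(spec):
    """Exact slanted-cut paraboloid volume by completing the square.

    Shifting coordinates to the footprint center turns the column height
    into C * (1 - r^2) over an ellipse with semiaxes sqrt(C/H0)*(A, B),
    giving V = pi*A*B*C^2 / (2*H0) with C = H0 + (A^2 tx^2 + B^2 ty^2)/(4 H0).
    """
    A, B, H0 = spec.A, spec.B, spec.H0
    tx, ty = spec.tilt_vector
    C = H0 + (A**2 * tx**2 + B**2 * ty**2) / (4.0 * H0)
    return np.pi * A * B * C**2 / (2.0 * H0) / 1000.0


def voxel_volume_ml(spec, h=0.2):
    """Midpoint Riemann sum of column heights on an h-mm lateral grid."""
    center, sx, sy = spec.footprint()
    x = np.arange(center[0] - sx, center[0] + sx + h, h)
    y = np.arange(center[1] - sy, center[1] + sy + h, h)
    X, Y = np.meshgrid(x + h / 2.0, y + h / 2.0)
    col = spec.cut_height(X, Y) - spec.surface_height(X, Y)
    return float(np.clip(col, 0.0, None).sum()) * h * h / 1000.0


def hemisphere_disk_sum_ml(radius, n):
    """Midpoint-rule disk sum for a hemisphere seen identically in two views.

    Disk i has diameter 2*sqrt(r^2 - d^2) at midpoint depth d from the flat
    base; the biplane sum is (pi L / 4n) * sum(d_i^2) with L = r.
    """
    L = radius
    d = (np.arange(1, n + 1) - 0.5) / n * L
    diam = 2.0 * np.sqrt(np.clip(radius**2 - d**2, 0.0, None))
    return np.pi * L / (4.0 * n) * np.sum(diam**2) / 1000.0
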