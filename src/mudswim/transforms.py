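"""Variance-stabilising transforms used before analysis.

Density responses entering the ANOVA are transformed with
``log10(x + 1)`` to correct heterogeneity of variance (zero catches are
common).  Regression inputs, which are positive cell means, use plain
``log10`` and fail loudly on non-positive values rather than silently
offsetting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log10_plus1", "inverse_log10_plus1", "log10_strict"]


def log10_plus1(x):
    """``log10(x + 1)`` elementwise; requires ``x >= 0``."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log10_plus1 requires non-negative input")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def inverse_log10_plus1(y):
    """Inverse of :func:`log10_plus1`."""
    arr = np.asarray(y, dtype=float)
    out = np.power(10.0, arr) - 1.0
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def log10_strict(x):
    """Plain ``log10`` that raises on any non-positive value."""
    arr = np.asarray(x, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError(
            "log10 requires strictly positive input; zero or negative cell "
            "means should be excluded upstream"
        )
    out = np.log10(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out
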