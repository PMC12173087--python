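"""Circular arithmetic helpers.

One convention package-wide: orientations live in [0, 360); signed angular
differences use the representative in [-180, 180). The half-open interval
resolves the tie at +/-180 to -180.
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap orientation(s) to [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def signed_diff_deg(a, b):
    """Signed circular difference a - b in [-180, 180)."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_signed_deg(angle):
    """Wrap signed angle(s) to [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0
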