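"""Triangle template matching.

A QRS complex in the rectified high-pass output looks like a narrow,
roughly symmetric triangle with steep sides.  The matching statistic is the
product of the two slope differences across a per-side span of ``s``
samples,

    t(i) = (y(i) - y(i-s)) * (y(i) - y(i+s)),

with only the positive part retained: the product is large and positive at
an apex (both differences positive), negative on monotone ramps, and small
on broadband noise, so the operation both accentuates R peaks and acts as a
selective filter against EMG-band noise.  Units are squared amplitude.

The per-side span covers 20 ms — half of a 40 ms template window, itself
chosen well below the 80–120 ms width of a normal QRS complex so that
abnormal beats still fit — giving s = floor(0.020 * fs), i.e. s = 7 at the
360 Hz working rate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["select_template_halfwidth", "triangle_match"]

#: Full width of the triangle template, seconds (one s-sample span per side).
TEMPLATE_WIDTH_S = 0.040


def select_template_halfwidth(fs: float) -> int:
    """Per-side segment length s = floor(0.020 * fs), clamped to >= 1."""
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    return max(1, int(TEMPLATE_WIDTH_S / 2 * fs))


def triangle_match(y: np.ndarray, s: int) -> np.ndarray:
    """Rectified slope-product matched filter.

    Parameters
    ----------
    y
        Rectified high-pass output (non-negative expected, not enforced).
    s
        Per-side segment length in samples.

    Returns
    -------
    Non-negative array, same length as ``y``.  The first and last ``s``
    samples are 0, since one of the two slope segments would reach outside
    the signal there.
    """
    y = np.asarray(y, dtype=np.float64)
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    if y.size <= 2 * s + 1:
        raise ValueError(
            f"signal of length {y.size} too short for template half-width "
            f"s={s} (needs > {2 * s + 1} samples)"
        )
    t = np.zeros_like(y)
    core = (y[s:-s] - y[: -2 * s]) * (y[s:-s] - y[2 * s :])
    np.maximum(core, 0.0, out=core)
    t[s:-s] = core
    return t
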