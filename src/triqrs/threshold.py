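"""Dynamic amplitude threshold.

Candidate QRS regions are the samples where the smoothed matched-filter
output l(i) exceeds a slowly varying threshold

    th(i) = beta * MA(i) + theta,

where MA is a long centered moving average of l (half-window M, i.e.
2M+1 samples ~ one heartbeat at the working rate), beta a dimensionless
multiplier controlling block width, and theta an additive offset in squared
amplitude units that suppresses false positives in quiet segments.

Defaults at the 360 Hz working rate: M = 150 (the 301-sample window that
minimised the detection error on the training data), beta = 2.5, and theta
estimated as one quarter of the mean of l over the initialisation buffer
("auto" mode).  A fixed theta = 206 is the value trained on the MIT-BIH
amplitude scale and is only meaningful on similarly scaled inputs; auto
mode makes the whole detector invariant to input gain, since l, MA and
theta all scale with the square of the gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .filters import RecursiveMovingMean, centered_mean

__all__ = [
    "ThresholdParams",
    "moving_average",
    "estimate_theta",
    "dynamic_threshold",
    "StreamingThreshold",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Tunables of the dynamic threshold th = beta*MA + theta."""

    m_half: int = 150
    beta: float = 2.5
    theta_mode: Literal["auto", "fixed"] = "auto"
    theta_fixed: float = 206.0

    def __post_init__(self) -> None:
        if self.m_half < 1:
            raise ValueError("M must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.theta_fixed < 0:
            raise ValueError("theta must be non-negative")
        if self.theta_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")


def moving_average(l: np.ndarray, m_half: int) -> np.ndarray:
    """Centered moving mean of half-window M over the smoothed signal."""
    return centered_mean(np.asarray(l, dtype=np.float64), m_half)


def estimate_theta(l_buffer: np.ndarray) -> float:
    """theta = mean(l)/4 over the initialisation buffer (auto mode)."""
    l_buffer = np.asarray(l_buffer, dtype=np.float64)
    if l_buffer.size == 0:
        raise ValueError("cannot estimate theta from an empty buffer")
    return float(np.mean(l_buffer)) / 4.0


def dynamic_threshold(
    l: np.ndarray, params: ThresholdParams, theta: float | None = None
) -> np.ndarray:
    """th(i) = beta * MA(i) + theta, pointwise.

    ``theta`` overrides the params-driven choice; otherwise fixed mode uses
    ``params.theta_fixed`` and auto mode estimates from the whole of ``l``
    (the pipeline passes a theta computed from its initialisation buffer
    instead, so that batch and streaming agree).
    """
    l = np.asarray(l, dtype=np.float64)
    if theta is None:
        theta = (
            params.theta_fixed
            if params.theta_mode == "fixed"
            else estimate_theta(l)
        )
    ma = moving_average(l, params.m_half)
    return params.beta * ma + theta


class StreamingThreshold:
    """Sample-by-sample th = beta*MA + theta with M-sample lookahead.

    The moving average is maintained by the recursive running-sum update
    MA(i+1) = MA(i) + (l(i+M+1) - l(i-M)) / (2M+1) (with periodic
    resynchronisation); theta must be fixed before streaming starts.
    """

    def __init__(self, params: ThresholdParams, theta: float):
        self._params = params
        self._theta = float(theta)
        self._mean = RecursiveMovingMean(params.m_half)
        self._pending: list[float] = []

    def push(self, l_value: float) -> float | None:
        """Push one smoothed sample; return th at the center when available."""
        w = self._mean.window
        if not self._mean.initialized:
            self._pending.append(float(l_value))
            if len(self._pending) < w:
                return None
            ma = self._mean.initialize(np.asarray(self._pending))
        else:
            ma = self._mean.step(l_value)
        return self._params.beta * ma + self._theta
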