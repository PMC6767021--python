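"""Detector pipeline: configuration, batch detection, streaming detection.

The detector runs six stages on a single-channel ECG at the working rate
(360 Hz by default):

    high-pass  ->  triangle template match  ->  low-pass
        ->  dynamic threshold  ->  candidate blocks  ->  peak search

All filters are zero-phase (centered windows), so stage outputs stay
aligned with the input and no group-delay compensation is needed.  Every
window length is derived from the sampling rate alone; the only trained
quantities are the threshold multiplier beta, the averaging half-window M,
and (in fixed mode) the offset theta.

Batch mode (:func:`detect`) processes a whole record at once and returns
the peak list together with a :class:`StageTrace` of the intermediate
signals.  Streaming mode (:class:`StreamingDetector`, :func:`detect_stream`)
consumes samples one at a time: internally it recomputes the stages in
small chunks with enough context overlap that every computed value is
bitwise identical to the batch computation, then closes candidate blocks
and resolves the refractory correction incrementally, emitting a peak as
soon as no future sample can change it.  On any finite input the emitted
peak set equals the batch output exactly.

Latency: the detector buffers ``init_buffer_samples`` (default 300, i.e.
0.833 s at 360 Hz) before the threshold offset can be fixed, and a
confirmed peak is emitted within the lookahead plus refractory budget
after its position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

import numpy as np

from .filters import (
    ECGSignal,
    highpass,
    lowpass,
    select_highpass_halfwindow,
    select_lowpass_halfwindow,
)
from .peaksearch import (
    CandidateBlock,
    PeakList,
    SearchParams,
    find_blocks,
    locate_peaks,
    refractory_correct,
)
from .template import select_template_halfwidth, triangle_match
from .threshold import ThresholdParams, dynamic_threshold, estimate_theta

__all__ = [
    "DetectorConfig",
    "StageTrace",
    "derive_config",
    "detect",
    "detect_stream",
    "latency",
    "StreamingDetector",
    "refine_peaks_to_raw",
]

#: Relative floor for the auto threshold offset: silent or near-silent input
#: would otherwise give theta = 0 and let numerical dust cross the threshold.
_THETA_DUST = 16.0 * np.finfo(np.float64).eps


@dataclass(frozen=True)
class DetectorConfig:
    """Complete parameter set of the detector.

    ``n_half``, ``s_half`` and ``l_half`` are derived from ``fs_work`` and
    the cut-offs when left as None (see :func:`derive_config`); ``m_half``
    scales with the working rate from its 360 Hz anchor of 150.
    """

    fs_work: float = 360.0
    hp_cutoff: float = 5.0
    lp_cutoff: float = 35.0
    n_half: int | None = None
    s_half: int | None = None
    l_half: int | None = None
    m_half: int | None = None
    beta: float = 2.5
    theta_mode: Literal["auto", "fixed"] = "auto"
    theta_fixed: float = 206.0
    refractory_ms: float = 272.0
    search_cap_ms: float = 60.0
    init_buffer_samples: int = 300

    def __post_init__(self) -> None:
        if self.fs_work <= 0:
            raise ValueError("fs_work must be positive")
        if not 0 < self.hp_cutoff < self.lp_cutoff < self.fs_work / 2:
            raise ValueError(
                "cut-offs must satisfy 0 < hp_cutoff < lp_cutoff < fs_work/2; "
                f"got hp={self.hp_cutoff}, lp={self.lp_cutoff}, "
                f"fs={self.fs_work}"
            )
        for name in ("n_half", "s_half", "l_half", "m_half"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.init_buffer_samples < 1:
            raise ValueError("init_buffer_samples must be >= 1")

    # -- derived accessors (filled values win over the selection rules) ----

    @property
    def N(self) -> int:
        return (
            self.n_half
            if self.n_half is not None
            else select_highpass_halfwindow(self.fs_work, self.hp_cutoff)
        )

    @property
    def s(self) -> int:
        return (
            self.s_half
            if self.s_half is not None
            else select_template_halfwidth(self.fs_work)
        )

    @property
    def L(self) -> int:
        return (
            self.l_half
            if self.l_half is not None
            else select_lowpass_halfwindow(self.fs_work, self.lp_cutoff)
        )

    @property
    def M(self) -> int:
        return (
            self.m_half
            if self.m_half is not None
            else max(1, round(150 * self.fs_work / 360.0))
        )

    @property
    def search_params(self) -> SearchParams:
        return SearchParams(self.refractory_ms, self.search_cap_ms)

    @property
    def threshold_params(self) -> ThresholdParams:
        return ThresholdParams(
            self.M, self.beta, self.theta_mode, self.theta_fixed
        )

    @property
    def min_signal_length(self) -> int:
        """Shortest input batch detection accepts (largest window + 1)."""
        return 2 * max(self.N, self.s, self.L, self.M) + 2

    def describe_limit(self) -> str:
        windows = {"M": self.M, "N": self.N, "L": self.L, "s": self.s}
        name = max(windows, key=windows.get)  # type: ignore[arg-type]
        return f"{name} (half-window {windows[name]})"


@dataclass(frozen=True)
class StageTrace:
    """Per-sample intermediate signals, aligned to the input timeline."""

    y: np.ndarray
    t: np.ndarray
    l: np.ndarray
    ma: np.ndarray
    th: np.ndarray
    theta: float
    blocks: list[CandidateBlock] = field(default_factory=list)


def derive_config(fs_work: float = 360.0, **overrides) -> DetectorConfig:
    """Build a :class:`DetectorConfig` for a working rate, applying overrides.

    At fs_work = 360 Hz with the default cut-offs this yields the standard
    parameter set (N, s, L, M) = (25, 7, 5, 150).
    """
    cfg = DetectorConfig(fs_work=fs_work)
    if overrides:
        cfg = replace(cfg, **overrides)
    # touch the derived values so inconsistent cut-offs fail here
    _ = cfg.N, cfg.s, cfg.L, cfg.M
    return cfg


def latency(cfg: DetectorConfig) -> float:
    """Initialisation latency in seconds: buffer length over working rate."""
    return cfg.init_buffer_samples / cfg.fs_work


def _theta_for(l: np.ndarray, cfg: DetectorConfig) -> float:
    """Threshold offset: fixed constant, or mean(l)/4 over the init buffer.

    Auto mode is floored at a machine-epsilon multiple of the buffer's peak
    so silent input cannot produce threshold-crossing numerical dust; the
    floor scales with the squared input gain, preserving gain invariance.
    """
    if cfg.theta_mode == "fixed":
        return float(cfg.theta_fixed)
    buf = l[: cfg.init_buffer_samples] if l.size > cfg.init_buffer_samples else l
    theta = estimate_theta(buf)
    return max(theta, _THETA_DUST * float(np.max(buf, initial=0.0)))


def detect(x: ECGSignal, cfg: DetectorConfig | None = None) -> tuple[PeakList, StageTrace]:
    """Run the full six-stage detector on a record at the working rate.

    The input's sampling rate must equal ``cfg.fs_work`` (resample first;
    see :mod:`triqrs.io`).  Deterministic: identical input and config give
    identical output.
    """
    if cfg is None:
        cfg = derive_config()
    if abs(x.fs - cfg.fs_work) > 1e-9:
        raise ValueError(
            f"input rate {x.fs} Hz differs from working rate {cfg.fs_work} Hz;"
            " resample first"
        )
    if len(x) < cfg.min_signal_length:
        raise ValueError(
            f"signal of length {len(x)} is too short: the limiting window is "
            f"{cfg.describe_limit()}, requiring > {cfg.min_signal_length - 1} "
            "samples"
        )
    y = highpass(x.samples, cfg.N)
    t = triangle_match(y, cfg.s)
    l = lowpass(t, cfg.L)
    theta = _theta_for(l, cfg)
    tparams = cfg.threshold_params
    th = dynamic_threshold(l, tparams, theta=theta)
    ma = (th - theta) / tparams.beta
    blocks = find_blocks(l, th)
    cands = locate_peaks(blocks, y, cfg.search_params, cfg.fs_work)
    peaks = refractory_correct(cands, y, cfg.search_params, cfg.fs_work)
    trace = StageTrace(y=y, t=t, l=l, ma=ma, th=th, theta=theta, blocks=blocks)
    return peaks, trace


def refine_peaks_to_raw(x: ECGSignal, peaks: PeakList, s: int) -> PeakList:
    """Snap each peak to the nearest raw-signal extremum within +-s samples.

    Detection runs on the rectified high-pass output; for reporting, the
    apex of |x| in a small neighbourhood is often preferable.  Refinement
    never moves a peak by more than ``s`` samples and preserves ordering
    (duplicates after snapping are collapsed).
    """
    arr = np.abs(x.samples)
    out: list[int] = []
    for p in peaks.indices:
        lo = max(0, int(p) - s)
        hi = min(arr.size, int(p) + s + 1)
        q = lo + int(np.argmax(arr[lo:hi]))
        if not out or q > out[-1]:
            out.append(q)
    return PeakList(np.asarray(out, dtype=np.int64), peaks.fs)


# ---------------------------------------------------------------------------
# Streaming detection
# ---------------------------------------------------------------------------

def _dev_valid(xc: np.ndarray, half: int) -> np.ndarray:
    """Centered deviation on the valid interior of a context slice.

    Same accumulation order as the batch kernel (j ascending over the
    window), so results are bitwise identical to whole-signal computation.
    """
    w = 2 * half + 1
    m = xc.size - 2 * half
    center = xc[half : half + m]
    acc = np.zeros(m)
    for j in range(w):
        acc += center - xc[j : j + m]
    return acc / w


class StreamingDetector:
    """Sample-by-sample detector with incremental, exact peak confirmation.

    ``push`` accepts one raw sample and returns the list of peak indices
    confirmed by that sample (usually empty); ``finalize`` flushes the
    remaining tail once the stream ends.  The union of all returned indices
    equals the batch :func:`detect` output on the same samples; a stream
    shorter than the detector's minimum signal length yields no peaks.
    """

    _CHUNK = 64  # recompute granularity, samples

    def __init__(self, cfg: DetectorConfig | None = None):
        self.cfg = cfg or derive_config()
        c = self.cfg
        self._x: list[float] = []
        self._xa = np.empty(0)
        self._y = np.empty(0)
        self._t = np.empty(0)
        self._l = np.empty(0)
        self._th = np.empty(0)
        self._theta: float | None = None
        self._scan = 0          # first l/th index not yet assigned to a block
        self._open_start: int | None = None
        self._pending: list[int] = []  # candidate indices awaiting resolution
        self._emitted: list[int] = []
        self._finalized = False

    # -- stage extension ----------------------------------------------------

    def _extend_stages(self) -> None:
        c = self.cfg
        n = self._xa.size
        N, s, L, M = c.N, c.s, c.L, c.M

        # y valid through n-1-N; the first N samples need the global
        # left reflect pad, so the prefix is recomputed wholesale while small
        y_hi = n - 1 - N
        if y_hi >= self._y.size:
            a = self._y.size
            if a < N:
                xc = np.pad(self._xa[: y_hi + N + 1], (N, 0), mode="reflect")
                self._y = np.abs(_dev_valid(xc, N))
            else:
                xc = self._xa[a - N : y_hi + N + 1]
                self._y = np.concatenate([self._y, np.abs(_dev_valid(xc, N))])

        # t valid through y_size-1-s (needs y(i+s)); first s samples are 0
        t_hi = self._y.size - 1 - s
        if t_hi >= self._t.size:
            a = self._t.size
            idx = np.arange(max(a, s), t_hi + 1)
            prod = (self._y[idx] - self._y[idx - s]) * (
                self._y[idx] - self._y[idx + s]
            )
            np.maximum(prod, 0.0, out=prod)
            new_t = np.concatenate([np.zeros(max(0, min(s, t_hi + 1) - a)), prod])
            self._t = np.concatenate([self._t, new_t])

        # l valid through t_size-1-L, reflect-padded at the global start
        l_hi = self._t.size - 1 - L
        if l_hi >= self._l.size:
            a = self._l.size
            if a < L:
                tc = np.pad(self._t[: l_hi + L + 1], (L, 0), mode="reflect")
                self._l = self._t[: l_hi + 1] - _dev_valid(tc, L)
            else:
                tc = self._t[a - L : l_hi + L + 1]
                dev = _dev_valid(tc, L)
                self._l = np.concatenate(
                    [self._l, tc[L : L + dev.size] - dev]
                )

        # theta fixes once the init buffer of l is available (or in fixed mode)
        if self._theta is None:
            if c.theta_mode == "fixed":
                self._theta = float(c.theta_fixed)
            elif self._l.size >= c.init_buffer_samples:
                self._theta = _theta_for(self._l, c)
        if self._theta is None:
            return

        # th valid through l_size-1-M, reflect-padded at the global start
        th_hi = self._l.size - 1 - M
        if th_hi >= self._th.size:
            a = self._th.size
            if a >= M:
                lc = self._l[a - M : th_hi + M + 1]
                ma = lc[M : M + (th_hi + 1 - a)] - _dev_valid(lc, M)
            else:
                lc = np.pad(self._l[: th_hi + M + 1], (M, 0), mode="reflect")
                ma = (self._l[: th_hi + 1] - _dev_valid(lc, M))[a:]
            new_th = c.beta * ma + self._theta
            self._th = np.concatenate([self._th, new_th])

    # -- block closing and candidate emission -------------------------------

    def _harvest(self) -> list[int]:
        """Close finished blocks, tile them, resolve refractory, emit."""
        c = self.cfg
        frontier = self._th.size  # l/th known for [0, frontier)
        cap = c.search_params.search_cap_samples(c.fs_work)
        min_dist = c.search_params.refractory_samples(c.fs_work)

        i = self._scan
        while i < frontier:
            above = self._l[i] > self._th[i]
            if self._open_start is None:
                if above:
                    self._open_start = i
            elif not above:
                blk = CandidateBlock(self._open_start, i - 1)
                self._pending.extend(
                    int(p)
                    for p in locate_peaks(
                        [blk], self._y, c.search_params, c.fs_work
                    )
                )
                self._open_start = None
            i += 1
        self._scan = frontier

        # earliest index a future candidate could take
        future_min = self._open_start if self._open_start is not None else frontier
        return self._emit_ready(future_min, min_dist)

    def _emit_ready(self, future_min: int, min_dist: int) -> list[int]:
        """Emit survivors of candidate clusters that no future sample can touch."""
        c = self.cfg
        out: list[int] = []
        while self._pending:
            # leading cluster: maximal chain with gaps < min_dist
            k = 1
            while (
                k < len(self._pending)
                and self._pending[k] - self._pending[k - 1] < min_dist
            ):
                k += 1
            cluster = self._pending[:k]
            # the cluster is closed only if no future candidate can chain to it
            if future_min - cluster[-1] < min_dist:
                break
            survivors = refractory_correct(
                np.asarray(cluster, dtype=np.int64),
                self._y,
                c.search_params,
                c.fs_work,
            )
            out.extend(int(p) for p in survivors.indices)
            del self._pending[:k]
        self._emitted.extend(out)
        return out

    # -- public API ----------------------------------------------------------

    def push(self, sample: float) -> list[int]:
        """Feed one sample; return peak indices confirmed by it."""
        if self._finalized:
            raise RuntimeError("push() after finalize()")
        self._x.append(float(sample))
        if len(self._x) - self._xa.size < self._CHUNK:
            return []
        self._xa = np.asarray(self._x, dtype=np.float64)
        self._extend_stages()
        if self._th.size == 0:
            return []
        return self._harvest()

    def finalize(self) -> list[int]:
        """End of stream: flush the tail and return the remaining peaks.

        Streams shorter than the batch minimum length yield no peaks.
        """
        if self._finalized:
            return []
        self._finalized = True
        c = self.cfg
        if len(self._x) < c.min_signal_length:
            return []
        signal = ECGSignal(np.asarray(self._x, dtype=np.float64), c.fs_work)
        peaks, _ = detect(signal, c)
        emitted = set(self._emitted)
        out = [int(p) for p in peaks.indices if int(p) not in emitted]
        self._emitted.extend(out)
        return out


def detect_stream(
    samples: Iterable[float], cfg: DetectorConfig | None = None
) -> Iterator[int]:
    """Stream peak indices from an iterable of raw samples.

    Wraps :class:`StreamingDetector`: peaks are yielded as soon as they are
    confirmed, and the tail is flushed when the iterable is exhausted.  The
    yielded set equals batch :func:`detect` on the same samples.
    """
    det = StreamingDetector(cfg)
    for sample in samples:
        yield from det.push(sample)
    yield from det.finalize()
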