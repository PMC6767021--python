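"""Block-based R-peak search with refractory-period error correction.

Detection proceeds in three steps on the smoothed matched-filter output
``l`` and its dynamic threshold ``th``:

1. ``find_blocks`` — the candidate blocks are the maximal runs of samples
   where l(i) strictly exceeds th(i).
2. ``locate_peaks`` — each block of width at most the search cap (60 ms,
   i.e. half of a normal 120 ms QRS width) contributes the argmax of the
   rectified high-pass output ``y`` inside it; wider blocks are tiled into
   consecutive sub-windows of at most the cap, one candidate per tile.
   Since y is also large at Q and S deflections, a single QRS complex can
   yield several candidates at this stage.
3. ``refractory_correct`` — consecutive R peaks cannot be closer than
   272 ms (a ceiling heart rate of roughly 220 bpm; 98 samples at 360 Hz).
   Whenever two candidates violate that distance the one with the smaller
   ``y`` amplitude is eliminated; elimination repeats until stable, always
   removing the globally smallest-amplitude member of any violating pair,
   which makes the result independent of scan direction.

Indices are 0-based and refer to the working-rate timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SearchParams",
    "CandidateBlock",
    "PeakList",
    "find_blocks",
    "locate_peaks",
    "refractory_correct",
]


@dataclass(frozen=True)
class SearchParams:
    """Refractory distance and search-window cap, both in milliseconds."""

    refractory_ms: float = 272.0
    search_cap_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.refractory_ms <= 0 or self.search_cap_ms <= 0:
            raise ValueError("refractory_ms and search_cap_ms must be positive")

    def refractory_samples(self, fs: float) -> int:
        return max(1, round(self.refractory_ms * fs / 1000.0))

    def search_cap_samples(self, fs: float) -> int:
        return max(1, round(self.search_cap_ms * fs / 1000.0))


@dataclass(frozen=True)
class CandidateBlock:
    """Maximal run [start, end] (inclusive) where l exceeds th."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty block [{self.start}, {self.end}]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PeakList:
    """Strictly increasing R-peak sample indices on the given timeline."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1:
            raise ValueError("peak indices must be 1-D")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


def find_blocks(l: np.ndarray, th: np.ndarray) -> list[CandidateBlock]:
    """Maximal runs of strict exceedance l(i) > th(i), in order."""
    l = np.asarray(l, dtype=np.float64)
    th = np.asarray(th, dtype=np.float64)
    if l.shape != th.shape:
        raise ValueError(
            f"signal/threshold length mismatch: {l.shape} vs {th.shape}"
        )
    above = l > th
    if not above.any():
        return []
    # run-length extraction: transitions of the boolean mask
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [CandidateBlock(int(a), int(b)) for a, b in zip(starts, ends)]


def locate_peaks(
    blocks: list[CandidateBlock],
    y: np.ndarray,
    params: SearchParams,
    fs: float,
) -> np.ndarray:
    """One candidate per search window: argmax of y, earliest on ties.

    Blocks wider than the cap are tiled into consecutive sub-windows of at
    most ``search_cap_samples`` starting at the block start; each tile
    emits its own argmax (duplicates within one QRS complex are merged
    later by the refractory correction).
    """
    y = np.asarray(y, dtype=np.float64)
    cap = params.search_cap_samples(fs)
    out: list[int] = []
    for blk in blocks:
        if blk.end >= y.size:
            raise IndexError(
                f"block [{blk.start}, {blk.end}] outside signal of "
                f"length {y.size}"
            )
        for lo in range(blk.start, blk.end + 1, cap):
            hi = min(lo + cap - 1, blk.end)
            # np.argmax returns the first maximum -> earliest-index tie-break
            out.append(lo + int(np.argmax(y[lo : hi + 1])))
    return np.asarray(out, dtype=np.int64)


def refractory_correct(
    candidates: np.ndarray,
    y: np.ndarray,
    params: SearchParams,
    fs: float,
) -> PeakList:
    """Eliminate candidates closer than the refractory distance.

    While any two surviving neighbours are closer than the refractory
    distance, the candidate with the smallest y amplitude among all
    violating pairs is removed (on equal amplitude the later index goes).
    Removing the globally weakest violator first makes the outcome
    independent of processing direction.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    if candidates.size and np.any(np.diff(candidates) < 0):
        raise ValueError("candidates must be sorted")
    y = np.asarray(y, dtype=np.float64)
    min_dist = params.refractory_samples(fs)
    survivors = sorted(set(int(c) for c in candidates))
    amp = {i: float(y[i]) for i in survivors}

    def violators(seq: list[int]) -> list[int]:
        bad: set[int] = set()
        for a, b in zip(seq, seq[1:]):
            if b - a < min_dist:
                bad.update((a, b))
        return sorted(bad)

    while True:
        bad = violators(survivors)
        if not bad:
            break
        # weakest amplitude; tie -> later index removed (earlier kept)
        victim = min(bad, key=lambda i: (amp[i], -i))
        survivors.remove(victim)
    return PeakList(np.asarray(survivors, dtype=np.int64), fs)
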