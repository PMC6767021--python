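"""Beat-by-beat detector evaluation.

Detected peaks are scored against reference annotations with one-to-one
matching inside a fixed time tolerance (the EC57 convention of +-150 ms by
default): references are visited chronologically and each is paired with
the nearest unmatched detection within tolerance (equidistant ties go to
the earlier detection).  From the resulting true positives (TP), missed
beats (FN) and spurious detections (FP) the three standard figures follow:

    sensitivity            S   = 100 * TP / (TP + FN)
    positive predictivity  P   = 100 * TP / (TP + FP)
    detection error rate   DER = 100 * (FN + FP) / (TP + FN)

S and P live in [0, 100]; DER is non-negative and can exceed 100 when the
detector produces more spurious beats than there are reference beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

import numpy as np

__all__ = [
    "MatchResult",
    "Metrics",
    "match_beats",
    "compute_metrics",
    "metrics_table",
    "DEFAULT_TOLERANCE_MS",
]

DEFAULT_TOLERANCE_MS = 150.0


@dataclass(frozen=True)
class MatchResult:
    """TP/FN/FP counts plus the matched (reference, detection) index pairs."""

    tp: int
    fn: int
    fp: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, positive predictivity and detection error rate, in %."""

    sensitivity: float
    positive_predictivity: float
    der: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(
            round(self.sensitivity, ndigits),
            round(self.positive_predictivity, ndigits),
            round(self.der, ndigits),
        )


def match_beats(
    reference: np.ndarray,
    detected: np.ndarray,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    fs: float = 360.0,
) -> MatchResult:
    """Greedy chronological one-to-one matching within +-tolerance.

    Both index lists must be sorted (raises otherwise).  Each reference
    beat claims the nearest still-unmatched detection within the tolerance;
    equidistant candidates resolve to the earlier detection.
    """
    reference = np.asarray(reference, dtype=np.int64)
    detected = np.asarray(detected, dtype=np.int64)
    for name, arr in (("reference", reference), ("detected", detected)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} indices must be sorted")
    tol = tolerance_ms * fs / 1000.0

    pairs: list[tuple[int, int]] = []
    used = np.zeros(detected.size, dtype=bool)
    lo = 0
    for r in reference:
        while lo < detected.size and (used[lo] or detected[lo] < r - tol):
            lo += 1
        best = -1
        best_d = None
        j = lo
        while j < detected.size and detected[j] <= r + tol:
            if not used[j]:
                d = abs(int(detected[j]) - int(r))
                if best_d is None or d < best_d:  # tie keeps the earlier
                    best, best_d = j, d
            j += 1
        if best >= 0:
            used[best] = True
            pairs.append((int(r), int(detected[best])))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fn=int(reference.size) - tp,
        fp=int(detected.size) - tp,
        pairs=pairs,
    )


def compute_metrics(m: MatchResult) -> Metrics:
    """S, P and DER (percent, 2-decimal rounding applies at reporting)."""
    if m.tp + m.fn == 0:
        raise ValueError("no reference beats: sensitivity and DER undefined")
    if m.tp + m.fp == 0:
        raise ValueError("no detections: positive predictivity undefined")
    return Metrics(
        sensitivity=100.0 * m.tp / (m.tp + m.fn),
        positive_predictivity=100.0 * m.tp / (m.tp + m.fp),
        der=100.0 * (m.fn + m.fp) / (m.tp + m.fn),
    )


def metrics_table(per_record: dict[str, MatchResult]) -> pd.DataFrame:
    """Per-record and aggregate metric table.

    Columns mirror the usual benchmark layout: Record, Total, TP, FN, FP,
    S(%), P(%), DER(%); the final row aggregates the counts over all
    records before recomputing the percentages.
    """
    rows = []
    for rec, m in per_record.items():
        met = compute_metrics(m).rounded()
        rows.append(
            {
                "Record": rec,
                "Total": m.n_reference,
                "TP": m.tp,
                "FN": m.fn,
                "FP": m.fp,
                "S(%)": met.sensitivity,
                "P(%)": met.positive_predictivity,
                "DER(%)": met.der,
            }
        )
    if len(per_record) > 1:
        total = MatchResult(
            tp=sum(m.tp for m in per_record.values()),
            fn=sum(m.fn for m in per_record.values()),
            fp=sum(m.fp for m in per_record.values()),
        )
        met = compute_metrics(total).rounded()
        rows.append(
            {
                "Record": "Total",
                "Total": total.n_reference,
                "TP": total.tp,
                "FN": total.fn,
                "FP": total.fp,
                "S(%)": met.sensitivity,
                "P(%)": met.positive_predictivity,
                "DER(%)": met.der,
            }
        )
    return pd.DataFrame(rows)
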