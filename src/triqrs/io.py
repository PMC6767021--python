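"""Record input/output: WFDB and CSV readers, resampling, peak writing.

Two input routes are supported:

* **WFDB** (PhysioNet) records: the text ``.hea`` header plus a binary
  ``.dat`` signal file in format 212 (12-bit packed pairs) or 16
  (little-endian int16), with optional MIT-format annotation files
  (``.atr`` and friends).  The reader is deliberately minimal — single
  segment, one ``.dat`` file per record — which covers the standard
  arrhythmia-database layout.
* **CSV/plain text**: one sample per line (optionally with a header row),
  with the sampling rate supplied by the caller.

Reference annotations are filtered to beat types only: the default
whitelist is the PhysioNet beat mnemonic set
(N L R B A a J S V r F e j n E f Q ?); non-beat annotations (rhythm
changes, noise markers, comments, ...) are dropped before evaluation.

All inputs can be brought to the common working rate (360 Hz) with
:func:`resample_to`, a rational-ratio polyphase resampler that also
rescales annotation indices (nearest sample).  Detected peaks are written
as CSV on the working timeline, with original-rate indices added when the
record was resampled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .filters import ECGSignal
from .peaksearch import PeakList

__all__ = [
    "RecordBundle",
    "read_record",
    "read_csv_signal",
    "read_wfdb_record",
    "read_wfdb_annotations",
    "resample_to",
    "write_peaks",
    "read_peaks",
    "BEAT_MNEMONICS",
]

#: PhysioNet beat annotation mnemonics kept for evaluation.
BEAT_MNEMONICS = frozenset("NLRBAaJSVrFejnEfQ?")

#: WFDB annotation code -> mnemonic (the standard code table).
_ANN_CODE_TO_MNEMONIC = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}


@dataclass(frozen=True)
class RecordBundle:
    """A record's signal, optional beat annotations, and identifier."""

    signal: ECGSignal
    annotations: np.ndarray | None
    record_id: str

    def __post_init__(self) -> None:
        if self.annotations is not None:
            ann = np.asarray(self.annotations, dtype=np.int64)
            object.__setattr__(self, "annotations", ann)
            if ann.size and (ann.min() < 0 or ann.max() >= len(self.signal)):
                raise ValueError("annotation indices outside signal range")
            if ann.size > 1 and np.any(np.diff(ann) < 0):
                raise ValueError("annotations must be sorted")


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

def read_csv_signal(path: str | Path, fs: float) -> RecordBundle:
    """Read a one-column CSV/text signal (header row tolerated)."""
    path = Path(path)
    values: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            token = row[0].strip()
            try:
                values.append(float(token))
            except ValueError:
                if values:  # header rows only make sense at the top
                    raise ValueError(f"non-numeric sample {token!r} in {path}")
    if not values:
        raise ValueError(f"no samples found in {path}")
    return RecordBundle(
        ECGSignal(np.asarray(values), fs), None, record_id=path.stem
    )


# ---------------------------------------------------------------------------
# WFDB input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_header(hea_path: Path) -> tuple[str, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header {hea_path}")
    head = lines[0].split()
    if len(head) < 2:
        raise ValueError(f"malformed WFDB record line in {hea_path}: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise ValueError(f"malformed WFDB signal line: {ln!r}")
        fmt_field = parts[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, adc_zero = 200.0, None, 0
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g = g.split("/")[0]
            if "(" in g:
                gain_s, rest = g.split("(")
                baseline = int(rest.rstrip(")"))
                gain = float(gain_s)
            else:
                gain = float(g)
            if gain == 0:
                gain = 200.0
        if len(parts) > 4:
            adc_zero = int(parts[4])
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(parts[9:]) if len(parts) > 9 else ""
        specs.append(_SignalSpec(parts[0], fmt, gain, baseline, desc))
    if len(specs) != nsig:
        raise ValueError(
            f"header {hea_path} declares {nsig} signals but lists {len(specs)}"
        )
    return record_name, fs, nsamp, specs


def _read_dat(path: Path, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    """Decode a multiplexed .dat file to an (nsamp, nsig) int array."""
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        total = (data.size // nsig) * nsig
        frames = data[:total].reshape(-1, nsig).astype(np.int32)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        usable = (b.size // 3) * 3
        b = b[:usable].reshape(-1, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1[s1 > 2047] -= 4096
        s2[s2 > 2047] -= 4096
        flat = np.empty(2 * s1.size, dtype=np.int32)
        flat[0::2] = s1
        flat[1::2] = s2
        total = (flat.size // nsig) * nsig
        frames = flat[:total].reshape(-1, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    if nsamp:
        frames = frames[:nsamp]
    return frames


def read_wfdb_record(record: str | Path, channel: int = 0) -> RecordBundle:
    """Read one channel of a WFDB record (formats 212 and 16).

    ``record`` is the path to the ``.hea`` file or the record name without
    extension.  ADC values are converted to physical units via
    (adc - baseline) / gain.
    """
    record = Path(record)
    hea_path = record if record.suffix == ".hea" else record.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    record_name, fs, nsamp, specs = _parse_header(hea_path)
    if not 0 <= channel < len(specs):
        raise ValueError(
            f"channel {channel} out of range: record has {len(specs)} signals"
        )
    spec = specs[channel]
    if any(s.filename != spec.filename for s in specs):
        raise ValueError("multi-file WFDB records are not supported")
    if any(s.fmt != spec.fmt for s in specs):
        raise ValueError("mixed-format WFDB records are not supported")
    dat_path = hea_path.parent / spec.filename
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    frames = _read_dat(dat_path, spec.fmt, len(specs), nsamp)
    physical = (frames[:, channel] - spec.baseline) / spec.gain
    return RecordBundle(ECGSignal(physical, fs), None, record_id=record_name)


def read_wfdb_annotations(
    path: str | Path,
    beats_only: bool = True,
    whitelist: frozenset[str] = BEAT_MNEMONICS,
) -> tuple[np.ndarray, list[str]]:
    """Read a MIT-format annotation file; return (indices, mnemonics).

    The format is a stream of little-endian 16-bit words: the upper 6 bits
    carry the annotation code, the lower 10 the time increment from the
    previous annotation.  Pseudo-codes handle long gaps (SKIP), auxiliary
    strings and field updates (NUM/SUB/CHN/AUX); code 0 with increment 0
    terminates the stream.  With ``beats_only`` the result is filtered to
    the beat whitelist.
    """
    data = Path(path).read_bytes()
    indices: list[int] = []
    symbols: list[str] = []
    time = 0
    i = 0
    while i + 1 < len(data):
        low, high = data[i], data[i + 1]
        i += 2
        code = high >> 2
        incr = ((high & 0x03) << 8) | low
        if code == 59:  # SKIP: next two words hold a 32-bit interval
            if i + 3 >= len(data):
                break
            interval = (
                (data[i + 1] << 24)
                | (data[i] << 16)
                | (data[i + 3] << 8)
                | data[i + 2]
            )
            if interval >= 1 << 31:
                interval -= 1 << 32
            time += interval
            i += 4
        elif code == 63:  # AUX: incr bytes of string, padded to even
            i += incr + (incr & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN field updates
            continue
        elif code == 0 and incr == 0:
            break
        else:
            time += incr
            mnemonic = _ANN_CODE_TO_MNEMONIC.get(code, "?")
            indices.append(time)
            symbols.append(mnemonic)
    if beats_only:
        keep = [k for k, s in enumerate(symbols) if s in whitelist]
        indices = [indices[k] for k in keep]
        symbols = [symbols[k] for k in keep]
    return np.asarray(indices, dtype=np.int64), symbols


def read_record(
    path: str | Path,
    channel: int = 0,
    fs: float | None = None,
    annotator: str | None = None,
) -> RecordBundle:
    """Read a WFDB record or a CSV signal, dispatching on the extension.

    CSV/TXT inputs require ``fs``; WFDB inputs may attach beat annotations
    from ``<record>.<annotator>`` (e.g. annotator ``"atr"``).
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        if fs is None:
            raise ValueError("CSV input requires an explicit sampling rate")
        return read_csv_signal(path, fs)
    bundle = read_wfdb_record(path, channel)
    if annotator:
        ann_path = path.with_suffix("." + annotator)
        if not ann_path.exists():
            raise FileNotFoundError(f"annotation file not found: {ann_path}")
        idx, _ = read_wfdb_annotations(ann_path)
        idx = idx[(idx >= 0) & (idx < len(bundle.signal))]
        bundle = replace(bundle, annotations=idx)
    return bundle


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(bundle: RecordBundle, fs_target: float = 360.0) -> RecordBundle:
    """Polyphase-resample a record to the target rate.

    The rational ratio fs_target/fs is applied with ``resample_poly``;
    annotation indices are rescaled by the same ratio and rounded to the
    nearest sample.  A matching rate returns the bundle unchanged
    (bit-exact).
    """
    if fs_target <= 0:
        raise ValueError("target rate must be positive")
    fs_src = bundle.signal.fs
    if fs_src == fs_target:
        return bundle
    ratio = Fraction(fs_target / fs_src).limit_denominator(1 << 16)
    resampled = resample_poly(bundle.signal.samples, ratio.numerator, ratio.denominator)
    ann = bundle.annotations
    if ann is not None:
        ann = np.round(ann * (fs_target / fs_src)).astype(np.int64)
        ann = np.clip(ann, 0, resampled.size - 1)
    return RecordBundle(
        ECGSignal(resampled, fs_target), ann, record_id=bundle.record_id
    )


# ---------------------------------------------------------------------------
# Peak output
# ---------------------------------------------------------------------------

def write_peaks(
    peaks: PeakList, path: str | Path, fs_original: float | None = None
) -> None:
    """Write peaks as CSV: sample_index, time_s [, original_index].

    ``fs_original`` adds the nearest-sample index on the source timeline
    when the record was resampled to the working rate.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["sample_index", "time_s"]
        if fs_original is not None:
            header.append("original_index")
        writer.writerow(header)
        for idx in peaks.indices:
            row = [int(idx), f"{idx / peaks.fs:.3f}"]
            if fs_original is not None:
                row.append(int(round(idx * fs_original / peaks.fs)))
            writer.writerow(row)


def read_peaks(path: str | Path, fs: float) -> PeakList:
    """Read a peak CSV written by :func:`write_peaks`."""
    indices: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        for row in reader:
            if row:
                indices.append(int(row[0]))
    return PeakList(np.asarray(indices, dtype=np.int64), fs)
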