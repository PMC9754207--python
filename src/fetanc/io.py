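"""Reading and writing multichannel ECG recordings and R-peak annotations.

Two on-disk formats are supported: delimited text (CSV, one column per
channel, optional header row) and the WFDB signal format restricted to
16-bit integer sample encoding (``format 16``), which is what the public
noninvasive fetal ECG benchmarks ship.  Peak annotations are plain-text
files with one 0-based sample index per line.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("abdominal", "thoracic", "ground_truth_fetal", "ground_truth_maternal", "other")


class FormatError(ValueError):
    """Raised when a file is structurally invalid for the declared format."""


@dataclass
class ECGRecord:
    """A multichannel ECG recording.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Amplitudes in arbitrary units (mV when the source declares units).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_roles : list of str
        One of ``abdominal``, ``thoracic``, ``ground_truth_fetal``,
        ``ground_truth_maternal``, ``other`` per channel.
    record_id : str
    """

    signals: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=list)
    channel_roles: list = field(default_factory=list)
    record_id: str = "record"

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signals.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        n = self.n_channels
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n)]
        if not self.channel_roles:
            self.channel_roles = ["other"] * n
        if len(self.channel_labels) != n or len(self.channel_roles) != n:
            raise ValueError("labels/roles must match channel count")
        for r in self.channel_roles:
            if r not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels_with_role(self, role: str) -> list:
        return [i for i, r in enumerate(self.channel_roles) if r == role]


@dataclass
class PeakAnnotations:
    """Sorted R-peak sample positions for one channel/source."""

    indices: np.ndarray
    fs: float
    label: str = "qrs"

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        if idx.size and idx.min() < 0:
            raise FormatError("negative annotation index")
        self.indices = np.unique(idx)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.indices.size

    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path, fs):
    if fs is None:
        raise ValueError("fs is required when reading csv records")
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",") if t.strip() != ""]

    def _numeric(tok):
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = tokens and not all(_numeric(t) for t in tokens)
    df = pd.read_csv(path, header=0 if has_header else None, float_precision="round_trip")
    labels, roles = [], []
    for col in df.columns:
        name = str(col)
        if has_header and "|" in name:
            lab, role = name.split("|", 1)
            labels.append(lab)
            roles.append(role if role in CHANNEL_ROLES else "other")
        elif has_header:
            labels.append(name)
            roles.append("other")
    sig = df.to_numpy(dtype=float).T
    if np.isnan(sig).any():
        raise FormatError(f"{path}: ragged or non-numeric csv content")
    return ECGRecord(sig, fs=fs, channel_labels=labels, channel_roles=roles or [],
                     record_id=os.path.splitext(os.path.basename(path))[0])


def _write_csv(record: ECGRecord, path):
    cols = [f"{lab}|{role}" for lab, role in zip(record.channel_labels, record.channel_roles)]
    pd.DataFrame(record.signals.T, columns=cols).to_csv(path, index=False,
                                                        float_format="%.17g")


# ---------------------------------------------------------------------------
# WFDB (format 16 only)
# ---------------------------------------------------------------------------

def _write_wfdb(record: ECGRecord, path):
    """Write ``path.hea`` + ``path.dat`` with 16-bit encoding.

    Gain per channel is chosen so the signal range spans most of the int16
    range; quantization error is bounded by half an ADC step.
    """
    base = os.path.splitext(path)[0]
    name = os.path.basename(base)
    n_ch, n = record.n_channels, record.n_samples
    gains, baselines, adc = [], [], np.empty((n_ch, n), dtype="<i2")
    for c in range(n_ch):
        amp = np.max(np.abs(record.signals[c]))
        gain = 30000.0 / amp if amp > 0 else 200.0
        q = np.clip(np.rint(record.signals[c] * gain), -32768, 32767)
        adc[c] = q.astype("<i2")
        gains.append(gain)
        baselines.append(0)
    with open(base + ".dat", "wb") as fh:
        fh.write(adc.T.tobytes())  # interleaved sample-major
    fs = record.fs
    fs_str = f"{fs:g}"
    lines = [f"{name} {n_ch} {fs_str} {n}"]
    for c in range(n_ch):
        desc = f"{record.channel_labels[c]}|{record.channel_roles[c]}"
        lines.append(
            f"{name}.dat 16 {gains[c]:.6f}({baselines[c]})/mV 16 0 {int(adc[c, 0])} 0 0 {desc}"
        )
    with open(base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_wfdb(path):
    base = os.path.splitext(path)[0]
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_ch = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n = int(head[3]) if len(head) > 3 else 0
    if len(lines) - 1 < n_ch:
        raise FormatError(f"{hea}: header lists {n_ch} signals but has {len(lines)-1} lines")
    gains, baselines, labels, roles, datfile = [], [], [], [], None
    for c in range(n_ch):
        parts = lines[1 + c].split(None, 8)
        datfile = parts[0]
        if parts[1].split("x")[0] != "16":
            raise FormatError(f"unsupported wfdb sample format {parts[1]!r} (only 16)")
        gspec = parts[2]
        gpart = gspec.split("/")[0]
        if "(" in gpart:
            g, b = gpart[:-1].split("(")
            gains.append(float(g))
            baselines.append(int(b))
        else:
            gains.append(float(gpart) if float(gpart) != 0 else 200.0)
            baselines.append(0)
        desc = parts[8] if len(parts) > 8 else f"ch{c}"
        if "|" in desc:
            lab, role = desc.split("|", 1)
        else:
            lab, role = desc, "other"
        labels.append(lab)
        roles.append(role if role in CHANNEL_ROLES else "other")
    dat = os.path.join(os.path.dirname(base) or ".", datfile)
    raw = np.fromfile(dat, dtype="<i2")
    if n == 0:
        n = raw.size // n_ch
    if raw.size < n * n_ch:
        raise FormatError(f"{dat}: expected {n * n_ch} samples, found {raw.size}")
    sig = raw[: n * n_ch].reshape(n, n_ch).T.astype(float)
    for c in range(n_ch):
        sig[c] = (sig[c] - baselines[c]) / gains[c]
    return ECGRecord(sig, fs=fs, channel_labels=labels, channel_roles=roles, record_id=name)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_record(path, format: str = None, fs: float = None) -> ECGRecord:
    """Read a recording from ``wfdb`` (.hea/.dat) or ``csv``.

    ``fs`` is required for csv (the file carries no rate); for wfdb it is
    taken from the header. ``format`` is inferred from the extension when
    omitted.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "wfdb" if ext in (".hea", ".dat", "") else "csv"
    if format == "csv":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return _read_csv(path, fs)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: ECGRecord, path, format: str = None) -> None:
    """Write a recording; csv round-trips exactly, wfdb within one ADC step."""
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "wfdb" if ext in (".hea", ".dat", "") else "csv"
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path, fs: float, label: str = "qrs", one_based: bool = False) -> PeakAnnotations:
    """Read a newline-separated list of sample indices.

    Indices are 0-based internally; files using 1-based positions must be
    declared with ``one_based=True`` and are shifted on read.  Duplicates
    are removed and the result is sorted.
    """
    idx = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            v = int(float(ln.split()[0]))
            idx.append(v - 1 if one_based else v)
    if any(v < 0 for v in idx):
        raise FormatError(f"{path}: negative sample index")
    return PeakAnnotations(np.asarray(idx, dtype=np.int64), fs=fs, label=label)


def write_annotations(ann: PeakAnnotations, path) -> None:
    with open(path, "w") as fh:
        for v in ann.indices:
            fh.write(f"{int(v)}\n")
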