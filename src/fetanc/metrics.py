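"""R-peak detection, beat matching and morphology metrics.

Detection follows the classic energy-based recipe (band-pass, derivative,
squaring, moving-window integration, adaptive threshold, refractory
period).  Matching scores a detector against reference annotations with a
one-to-one assignment at a +/-50 ms window, from which sensitivity,
positive predictive value and F1 are computed:

    SE  = 100 * TP / (TP + FN)
    PPV = 100 * TP / (TP + FP)
    F1  = 100 * 2 TP / (2 TP + FP + FN)

Morphology agreement between a ground-truth fetal waveform x and an
extracted waveform x_hat is quantified by MSE, SNR = 10 log10(sum x^2 /
sum (x - x_hat)^2) and Pearson's R, optionally after an affine
(sign/scale) re-fit that removes the BSS amplitude indeterminacy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .io import PeakAnnotations

SNR_CAP_DB = 100.0


@dataclass
class PeakMatchResult:
    TP: int
    FP: int
    FN: int
    SE: float
    PPV: float
    F1: float
    window_ms: float
    matched_pairs: list


@dataclass
class MorphologyMetrics:
    MSE: float
    SNR: float
    R: float


def detect_r_peaks(x: np.ndarray, fs: float, hr_range_bpm=(100, 200)) -> PeakAnnotations:
    """Energy-based QRS detection with adaptive threshold.

    ``hr_range_bpm`` sets the refractory period (60/high seconds) and is
    (100, 200) for fetal, (50, 120) for maternal beats.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if not np.any(x):
        return PeakAnnotations(np.empty(0, dtype=np.int64), fs=fs)
    high = min(40.0, 0.45 * fs)
    sos = sps.butter(3, [5.0, high], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, x)
    energy = np.gradient(f) ** 2
    win = max(3, int(round(0.08 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    refractory = max(1, int(round(60.0 / hr_range_bpm[1] * fs)))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        return PeakAnnotations(np.empty(0, dtype=np.int64), fs=fs)
    heights = integ[cand]
    thr = 0.25 * np.percentile(heights, 90)
    cand = cand[heights >= thr]
    # refine to the local extremum of the band-passed signal
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for p in cand:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(f[lo:hi]))))
    refined = np.unique(refined)
    # enforce refractory after refinement (keep larger |f| of close pairs)
    keep = []
    for p in refined:
        if keep and p - keep[-1] < refractory:
            if abs(f[p]) > abs(f[keep[-1]]):
                keep[-1] = p
        else:
            keep.append(p)
    return PeakAnnotations(np.asarray(keep, dtype=np.int64), fs=fs)


def match_peaks(detected: PeakAnnotations, reference: PeakAnnotations,
                fs: float = None, window_ms: float = 50.0) -> PeakMatchResult:
    """One-to-one beat matching within |dt| <= window_ms.

    The assignment maximizes the number of matched pairs and, among
    maximal matchings, minimizes the total |dt| (solved as a rectangular
    assignment problem).  Empty denominators define the statistic as 0.
    """
    fs = fs or detected.fs
    if detected.fs != reference.fs:
        raise ValueError("annotations must share a sampling rate")
    det = detected.indices.astype(float)
    ref = reference.indices.astype(float)
    window = window_ms / 1000.0 * fs
    pairs = []
    if det.size and ref.size:
        dist = np.abs(det[:, None] - ref[None, :])
        feasible = dist <= window
        # feasible pairs get a large bonus so cardinality dominates cost
        K = window * (det.size + ref.size + 1) + 1.0
        cost = np.where(feasible, dist - K, 0.0)
        rows, cols = linear_sum_assignment(cost)
        pairs = [(int(detected.indices[r]), int(reference.indices[c]))
                 for r, c in zip(rows, cols) if feasible[r, c]]
    tp = len(pairs)
    fp = det.size - tp
    fn = ref.size - tp
    se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    ppv = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return PeakMatchResult(TP=tp, FP=int(fp), FN=int(fn), SE=se, PPV=ppv, F1=f1,
                           window_ms=window_ms, matched_pairs=pairs)


def morphology_metrics(truth: np.ndarray, extracted: np.ndarray,
                       align: bool = True) -> MorphologyMetrics:
    """MSE, SNR (dB, capped at 100) and Pearson R of extracted vs truth.

    ``align=True`` first re-fits extracted = a*extracted + b by least
    squares against truth, removing the sign/scale ambiguity left by BSS.
    """
    x = np.asarray(truth, dtype=float).ravel()
    xh = np.asarray(extracted, dtype=float).ravel()
    if x.size != xh.size:
        raise ValueError("signals must have equal length")
    if x.std() == 0:
        raise ValueError("zero-variance ground truth: R undefined")
    if align:
        if xh.std() == 0:
            raise ValueError("zero-variance extraction cannot be aligned")
        A = np.vstack([xh, np.ones_like(xh)]).T
        (a, b), *_ = np.linalg.lstsq(A, x, rcond=None)
        xh = a * xh + b
    err = x - xh
    mse = float(np.mean(err**2))
    p_sig = float(np.sum(x**2))
    p_err = float(np.sum(err**2))
    snr = SNR_CAP_DB if p_err == 0 else min(SNR_CAP_DB, 10.0 * np.log10(p_sig / p_err))
    if xh.std() == 0:
        import warnings
        warnings.warn("zero-variance extraction: R undefined (NaN)", stacklevel=2)
        r = float("nan")
    else:
        r = float(np.corrcoef(x, xh)[0, 1])
    return MorphologyMetrics(MSE=mse, SNR=float(snr), R=r)


def fhr_trace(peaks: PeakAnnotations, smooth_beats: int = 5):
    """Beat-to-beat fetal heart rate (bpm), median-filtered over 5 beats.

    Returns (times_s, bpm) at the midpoints of successive RR intervals.
    """
    idx = peaks.indices
    if idx.size < 2:
        return np.empty(0), np.empty(0)
    rr = np.diff(idx) / peaks.fs
    bpm = 60.0 / rr
    if smooth_beats > 1 and bpm.size >= smooth_beats:
        k = smooth_beats + (smooth_beats % 2 == 0)  # odd kernel
        bpm = sps.medfilt(bpm, kernel_size=min(k, bpm.size - (bpm.size + 1) % 2))
    t = (idx[1:] + idx[:-1]) / 2.0 / peaks.fs
    return t, bpm
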