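"""Synthetic abdominal ECG generator.

Emulates the additive observation model of noninvasive fetal ECG:

    AECG(t) = MECG(t) + FECG(t) + n(t)

where the abdominal maternal component MECG is a nonlinear transform of a
thoracic maternal source (per-channel FIR + gain + smooth tanh saturation
+ latency, emulating volume-conduction diversity across electrode sites),
the fetal component is a faster, much weaker ECG train, and n(t) mixes
baseline wander, powerline interference and broadband noise calibrated in
dB relative to the fetal signal power:

    noise_level_db = 10 * log10(P_fetal / P_noise)

so 0 dB means noise as strong as the fetal signal.  Every component and
the true R-peak trains are returned as ground truth, and the additive
identity holds exactly per channel.

ECG morphology uses the standard five-Gaussian (P, Q, R, S, T) template
parameterization familiar from dynamical ECG models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import ECGRecord, PeakAnnotations


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass
class ECGTemplateParams:
    """Five-Gaussian cardiac-cycle template.

    ``centers`` are phases in [0, 1) of the cycle, ``widths`` are Gaussian
    standard deviations in cycle fraction, ``amplitudes`` in arbitrary
    units with the R wave dominant.
    """

    amplitudes: tuple = (0.12, -0.14, 1.0, -0.22, 0.28)  # P Q R S T
    centers: tuple = (0.16, 0.31, 0.36, 0.41, 0.65)
    widths: tuple = (0.035, 0.012, 0.016, 0.013, 0.065)
    scale: float = 1.0

    def __post_init__(self):
        if len(self.amplitudes) != 5 or len(self.centers) != 5 or len(self.widths) != 5:
            raise ValueError("template needs 5 waves (P,Q,R,S,T)")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if any(not (0 <= c < 1) for c in self.centers):
            raise ValueError("centers must lie in [0,1)")
        if max(abs(a) for a in self.amplitudes) != abs(self.amplitudes[2]):
            raise ValueError("R amplitude must dominate")

    @property
    def r_center(self) -> float:
        return self.centers[2]


#: Narrower, lower-amplitude complex typical of the fetal heart.
FETAL_TEMPLATE = ECGTemplateParams(
    amplitudes=(0.10, -0.12, 1.0, -0.18, 0.22),
    centers=(0.18, 0.32, 0.36, 0.40, 0.62),
    widths=(0.03, 0.010, 0.012, 0.010, 0.05),
)

MATERNAL_TEMPLATE = ECGTemplateParams()


def gaussian_ecg_cycle(params: ECGTemplateParams, fs: float, rr: float) -> np.ndarray:
    """One cardiac cycle of length round(rr*fs) as a sum of five Gaussians."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    n = int(round(rr * fs))
    if n < 10:
        raise ValueError(f"cycle of {n} samples is too short (rr*fs >= 10 required)")
    phase = np.arange(n) / n
    y = np.zeros(n)
    for a, c, w in zip(params.amplitudes, params.centers, params.widths):
        y += a * np.exp(-0.5 * ((phase - c) / w) ** 2)
    return params.scale * y


def synthesize_ecg_train(params: ECGTemplateParams, hr_mean: float, hr_sd: float,
                         fs: float, duration: float, seed) -> tuple:
    """Concatenate cycles with per-beat RR ~ truncated normal; returns
    (signal, R-peak annotations).  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    rr_mean = 60.0 / hr_mean
    rr_sd = 60.0 * hr_sd / hr_mean**2  # delta-method sd of RR
    n_total = int(round(duration * fs))
    sig = np.zeros(n_total)
    peaks = []
    pos = 0
    while pos < n_total:
        rr = rr_mean if hr_sd == 0 else float(
            np.clip(rng.normal(rr_mean, rr_sd), 0.5 * rr_mean, 1.5 * rr_mean))
        cyc = gaussian_ecg_cycle(params, fs, rr)
        n_c = cyc.size
        end = min(pos + n_c, n_total)
        sig[pos:end] += cyc[: end - pos]
        r_idx = pos + int(round(params.r_center * n_c))
        if r_idx < n_total:
            peaks.append(r_idx)
        pos += n_c
    return sig, PeakAnnotations(np.asarray(peaks), fs=fs, label="qrs")


# ---------------------------------------------------------------------------
# thoracic -> abdominal maternal channel transform
# ---------------------------------------------------------------------------

@dataclass
class ChannelTransformParams:
    """A concrete nonlinear volume-conduction model: FIR shaping, gain,
    smooth tanh saturation (identity at strength 0) and latency."""

    kernel: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    gain: float = 1.0
    saturation: float = 0.0
    latency: int = 0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float).ravel()
        if self.kernel.size < 1:
            raise ValueError("kernel must have at least one tap")
        if self.gain == 0:
            raise ValueError("gain must be nonzero")
        if self.saturation < 0:
            raise ValueError("saturation strength must be >= 0")


def _saturate(u: np.ndarray, s: float) -> np.ndarray:
    # tanh(s*u)/s -> u as s -> 0; monotone and bounded by 1/s for s > 0
    if s == 0:
        return u
    return np.tanh(s * u) / s


def abdominal_channel_transform(thoracic: np.ndarray, params: ChannelTransformParams) -> np.ndarray:
    """saturate(gain * FIR(x)) delayed by ``latency``, same length."""
    x = np.asarray(thoracic, dtype=float)
    if params.kernel.size >= x.size:
        raise ValueError("kernel longer than signal")
    filt = np.convolve(x, params.kernel)[: x.size]
    y = _saturate(params.gain * filt, params.saturation)
    if params.latency > 0:
        y = np.concatenate([np.zeros(params.latency), y[: x.size - params.latency]])
    elif params.latency < 0:
        lag = -params.latency
        y = np.concatenate([y[lag:], np.zeros(lag)])
    return y


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def generate_noise(kind: str, target_power: float, fs: float, n: int, seed,
                   powerline_hz: float = 50.0) -> np.ndarray:
    """One noise component scaled to exact mean power ``target_power``.

    baseline_wander : Gaussian noise low-passed below 0.5 Hz
    powerline       : sinusoid at ``powerline_hz`` with random phase
    broadband       : white Gaussian
    """
    if target_power < 0:
        raise ValueError("target_power must be >= 0")
    rng = np.random.default_rng(seed)
    if target_power == 0:
        return np.zeros(n)
    if kind == "broadband":
        x = rng.standard_normal(n)
    elif kind == "powerline":
        phase = rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * powerline_hz * np.arange(n) / fs + phase)
    elif kind == "baseline_wander":
        w = rng.standard_normal(n)
        sos = sps.butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, w)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    p = np.mean(x**2)
    if p == 0:
        return np.zeros(n)
    return x * np.sqrt(target_power / p)


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    fs: float = 250.0
    duration: float = 60.0
    n_abdominal_channels: int = 4
    maternal_hr_bpm: tuple = (82.0, 2.0)      # (mean, sd)
    fetal_hr_bpm: tuple = (140.0, 4.0)
    fetal_to_maternal_amplitude_ratio: float = 0.2
    noise_level_db: float = 0.0
    noise_weights: dict = field(default_factory=lambda: {
        "baseline_wander": 0.3, "powerline": 0.2, "broadband": 0.5})
    powerline_hz: float = 50.0
    thoracic_noise_power_frac: float = 1e-4   # broadband on the chest lead
    seed: int = 0

    def validate(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0 < self.fetal_to_maternal_amplitude_ratio < 1):
            raise ValueError("fetal/maternal ratio must lie in (0,1)")
        if not (50 <= self.maternal_hr_bpm[0] <= 120):
            raise ValueError("maternal heart rate outside physiological range")
        if not (100 <= self.fetal_hr_bpm[0] <= 200):
            raise ValueError("fetal heart rate outside physiological range")
        if self.n_abdominal_channels < 1:
            raise ValueError("need at least one abdominal channel")


@dataclass
class SimulatedRecording:
    record: ECGRecord
    truth_mecg: np.ndarray    # [n_abd, n]
    truth_fecg: np.ndarray
    truth_noise: np.ndarray
    fetal_peaks: PeakAnnotations
    maternal_peaks: PeakAnnotations
    config: SimConfig = None

    @property
    def abdominal_indices(self):
        return self.record.channels_with_role("abdominal")

    @property
    def thoracic_index(self):
        return self.record.channels_with_role("thoracic")[0]


def _median_r_amplitude(x: np.ndarray, peaks: PeakAnnotations, halfwin: int = 0) -> float:
    """Median |amplitude| at the peaks; ``halfwin`` searches the local max
    nearby (for signals shifted/smeared by a channel transform)."""
    idx = peaks.indices[peaks.indices < x.size]
    if not idx.size:
        return 0.0
    if halfwin == 0:
        return float(np.median(np.abs(x[idx])))
    vals = [np.max(np.abs(x[max(p - halfwin, 0): p + halfwin + 1])) for p in idx]
    return float(np.median(vals))


def simulate_recording(config: SimConfig = None) -> SimulatedRecording:
    """Generate one multichannel recording with exact additive ground truth."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    # independent substreams: beat times do not move when noise params change
    seed_m, seed_f, seed_ch, seed_nz, seed_th = rng.integers(0, 2**31 - 1, size=5)

    fs, dur = config.fs, config.duration
    n = int(round(fs * dur))
    thoracic_clean, maternal_peaks = synthesize_ecg_train(
        MATERNAL_TEMPLATE, *config.maternal_hr_bpm, fs, dur, seed_m)
    fetal_base, fetal_peaks = synthesize_ecg_train(
        FETAL_TEMPLATE, *config.fetal_hr_bpm, fs, dur, seed_f)

    ch_rng = np.random.default_rng(seed_ch)
    nz_rng = np.random.default_rng(seed_nz)
    k = config.n_abdominal_channels
    mecg = np.zeros((k, n))
    fecg = np.zeros((k, n))
    noise = np.zeros((k, n))
    for c in range(k):
        taps = np.concatenate([[1.0], ch_rng.normal(0, 0.15, size=ch_rng.integers(2, 6))])
        tr = ChannelTransformParams(
            kernel=taps,
            gain=float(ch_rng.uniform(0.7, 1.4)),
            saturation=float(ch_rng.uniform(0.2, 0.6)),
            latency=int(ch_rng.integers(0, 6)),
        )
        mecg[c] = abdominal_channel_transform(thoracic_clean, tr)

        # per-channel fetal projection: gain diversity + small latency
        f_gain = float(ch_rng.uniform(0.7, 1.3))
        f_lat = int(ch_rng.integers(0, 4))
        f = np.roll(fetal_base, f_lat) * f_gain
        f[:f_lat] = 0.0
        m_amp = _median_r_amplitude(mecg[c], maternal_peaks, halfwin=10)
        f_amp = _median_r_amplitude(f, PeakAnnotations(
            np.clip(fetal_peaks.indices + f_lat, 0, n - 1), fs))
        if f_amp > 0:
            f *= config.fetal_to_maternal_amplitude_ratio * m_amp / f_amp
        fecg[c] = f

        p_fetal = np.mean(fecg[c] ** 2)
        p_noise = p_fetal / 10 ** (config.noise_level_db / 10)
        wsum = sum(config.noise_weights.values())
        nz = np.zeros(n)
        for kind, w in config.noise_weights.items():
            sub = int(nz_rng.integers(0, 2**31 - 1))
            nz += generate_noise(kind, p_noise * w / wsum, fs, n, sub,
                                 powerline_hz=config.powerline_hz)
        p = np.mean(nz**2)
        if p > 0:
            nz *= np.sqrt(p_noise / p)  # exact total power after mixing
        noise[c] = nz

    th_rng = np.random.default_rng(seed_th)
    p_th = np.mean(thoracic_clean**2) * config.thoracic_noise_power_frac
    thoracic = thoracic_clean + generate_noise(
        "broadband", p_th, fs, n, int(th_rng.integers(0, 2**31 - 1)))

    signals = np.vstack([mecg + fecg + noise, thoracic[None, :]])
    labels = [f"ABD{c + 1}" for c in range(k)] + ["THX1"]
    roles = ["abdominal"] * k + ["thoracic"]
    record = ECGRecord(signals, fs=fs, channel_labels=labels, channel_roles=roles,
                       record_id=f"sim{config.seed}")
    return SimulatedRecording(record, mecg, fecg, noise, fetal_peaks, maternal_peaks,
                              config=config)
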