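"""The two adaptive-noise-cancelling stages built on TCED-Net.

Stage 1 (maternal ECG elimination): the network maps the thoracic reference
onto the abdominal channel by minimizing the mean squared error against the
abdominal signal itself.  Because the fetal ECG and noise are uncorrelated
with the thoracic reference, the error decomposes as

    eps = E[(M - y)^2] + E[F^2] + E[n^2]

so minimizing it drives the output y to the abdominal maternal component M
while the fetal power and noise power form an irreducible floor; the fetal
signal is recovered as the residual F_hat = AECG - y.  The abdominal
maternal component is the "ground truth" only in expectation — the
realizable regression target is the abdominal ECG, and convergence to M
follows from the uncorrelatedness of the other components.

Stage 2 (fetal denoising): each stage-1 residual channel in turn becomes
the primary; the network maps every *other* residual channel onto it.  The
fetal component is (nonlinearly) correlated across channels while residual
maternal ECG and noise are not, so the network *output* y_hat_i — not the
residual — converges to the primary channel's clean fetal component.

Both stages fit online, per record, whole-signal batch, with Adam; the
converged weights are record-specific and are not reused across records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tced import Adam, TCEDConfig, TCEDNet, init_network, pad_signal


class DivergenceError(RuntimeError):
    """Online optimization produced a non-finite loss."""


class NotEnoughReferencesError(ValueError):
    """Stage-2 denoising needs at least two channels."""


class InsufficientBeatsError(ValueError):
    """Too few detected maternal beats to build a template reference."""


@dataclass
class ANCResult:
    """One online fit: network estimate, residual and the loss trace.

    ``estimate + residual == target`` holds exactly by construction.
    """

    estimate: np.ndarray
    residual: np.ndarray
    loss_trace: np.ndarray
    epochs_run: int
    seed: int

    @property
    def final_loss(self) -> float:
        """Mean squared error of the final (evaluation-mode) estimate."""
        return float(np.mean(self.residual**2))


@dataclass
class DenoiseSet:
    """Stage-2 outputs: one fetal estimate per reference channel."""

    estimates: list
    primary_index: int
    reference_indices: list


def fit_online(input_ref: np.ndarray, target: np.ndarray, config: TCEDConfig = None,
               epochs: int = 100, seed: int = 0, lr: float = None, normalize: bool = True,
               early_stop: bool = False, patience: int = 20, rel_tol: float = 1e-4):
    """Fit TCED-Net to map ``input_ref`` onto ``target`` by whole-record MSE.

    Returns ``(net, ANCResult)``.  With ``normalize=True`` (default) the
    fit runs in standardized coordinates — both signals z-scored, the
    estimate mapped back to target units — so optimizer conditioning does
    not depend on the signals' scale; the additive identity
    ``estimate + residual == target`` is unaffected.  The loss trace holds
    the training-mode MSE of each epoch (in normalized units, before that
    epoch's update); the final estimate is an evaluation-mode forward pass
    (dropout off, current-record normalization statistics).
    """
    config = config or TCEDConfig.reduced()
    x = np.asarray(input_ref, dtype=float).ravel()
    t_orig = np.asarray(target, dtype=float).ravel()
    if x.size != t_orig.size:
        raise ValueError("input and target must have equal length")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n = x.size
    if normalize:
        mu_t, sd_t = t_orig.mean(), t_orig.std()
        sd_t = sd_t if sd_t > 0 else 1.0
        sd_x = x.std() if x.std() > 0 else 1.0
        x = (x - x.mean()) / sd_x
        t = (t_orig - mu_t) / sd_t
    else:
        mu_t, sd_t = 0.0, 1.0
        t = t_orig
    xp, _ = pad_signal(x, config.length_multiple)
    tp, _ = pad_signal(t, config.length_multiple)
    net = init_network(config, c_in=1, c_out=1, seed=seed)
    opt = Adam(net.parameters(), lr=lr if lr is not None else config.learning_rate)
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))

    trace = []
    best, since_best = np.inf, 0
    for epoch in range(epochs):
        y = net.forward(xp, train=True, rng=drop_rng)
        err = y[0, :n] - tp[0, :n]
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        trace.append(loss)
        net.zero_grad()
        dy = np.zeros_like(y)
        dy[0, :n] = 2.0 * err / n
        net.backward(dy)
        opt.step()
        if early_stop:
            if loss < best * (1 - rel_tol):
                best, since_best = loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
    estimate = net.forward(xp, train=False)[0, :n] * sd_t + mu_t
    result = ANCResult(estimate=estimate, residual=t_orig - estimate,
                       loss_trace=np.asarray(trace), epochs_run=len(trace), seed=seed)
    return net, result


def eliminate_mecg(aecg_channel: np.ndarray, thoracic_ref: np.ndarray,
                   config: TCEDConfig = None, epochs: int = 100, seed: int = 0) -> ANCResult:
    """Stage 1: estimate the abdominal maternal ECG from the thoracic
    reference and subtract it.  ``estimate`` is M_hat, ``residual`` the
    noisy fetal signal F_hat."""
    _, result = fit_online(thoracic_ref, aecg_channel, config=config, epochs=epochs, seed=seed)
    return result


def denoise_fecg(channels: list, primary_index: int, config: TCEDConfig = None,
                 epochs: int = 200, seed: int = 0) -> DenoiseSet:
    """Stage 2: map each reference residual channel onto the primary one.

    Returns the network *outputs* y_hat_i (the fetal estimates), one per
    reference channel; a fresh network (fresh seeded initialization) is
    fit per reference.
    """
    k = len(channels)
    if k < 2:
        raise NotEnoughReferencesError("stage-2 denoising needs >= 2 channels")
    primary = np.asarray(channels[primary_index], dtype=float).ravel()
    refs = [i for i in range(k) if i != primary_index]
    estimates = []
    for j, i in enumerate(refs):
        sub_seed = int(np.random.SeedSequence([seed, primary_index, i]).generate_state(1)[0]
                       % (2**31 - 1))
        _, res = fit_online(channels[i], primary, config=config, epochs=epochs, seed=sub_seed)
        estimates.append(res.estimate)
    return DenoiseSet(estimates=estimates, primary_index=primary_index, reference_indices=refs)


def build_synthetic_thoracic(aecg_channel: np.ndarray, fs: float,
                             window_s: float = 0.35) -> np.ndarray:
    """Average-maternal-cycle reference for recordings without a chest lead.

    Maternal R peaks are detected on the abdominal channel (the maternal
    QRS dominates in amplitude), windows of +/-``window_s`` around each
    peak are averaged into a template, and the template is overlap-added
    at every detected peak over a zero baseline.
    """
    from .metrics import detect_r_peaks

    x = np.asarray(aecg_channel, dtype=float).ravel()
    peaks = detect_r_peaks(x, fs, hr_range_bpm=(50, 120)).indices
    if peaks.size < 3:
        raise InsufficientBeatsError(f"only {peaks.size} maternal beats detected")
    half = int(round(window_s * fs))
    template = np.zeros(2 * half + 1)
    counts = np.zeros(2 * half + 1)
    for p in peaks:
        lo, hi = p - half, p + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, x.size)
        template[s_lo - lo: s_lo - lo + (s_hi - s_lo)] += x[s_lo:s_hi]
        counts[s_lo - lo: s_lo - lo + (s_hi - s_lo)] += 1
    template /= np.maximum(counts, 1)
    out = np.zeros_like(x)
    for p in peaks:
        lo, hi = p - half, p + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, x.size)
        out[s_lo:s_hi] += template[s_lo - lo: s_lo - lo + (s_hi - s_lo)]
    return out
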