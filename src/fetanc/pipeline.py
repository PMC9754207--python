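"""End-to-end orchestration: preprocess -> stage-1 maternal elimination ->
stage-2 cross-channel denoising -> JADE -> evaluation.

The pipeline is deterministic given (record, config, seed): per-stage seeds
are derived from the master seed with a SeedSequence, and every fitted
network is freshly initialized from its derived seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .anc import build_synthetic_thoracic, denoise_fecg, eliminate_mecg
from .io import ECGRecord, PeakAnnotations
from .jade import jade_separate, select_fetal_component
from .metrics import detect_r_peaks, fhr_trace, match_peaks, morphology_metrics
from .preprocess import FilterSpec, preprocess_channel
from .tced import TCEDConfig

logger = logging.getLogger("fetanc")


def _stage1_config() -> TCEDConfig:
    # high-SNR thoracic reference: the online fit converges to the noise
    # floor fastest without dropout and with a larger step for the
    # reduced-capacity network
    return TCEDConfig.reduced(learning_rate=1e-2, dropout_rate=0.0)


def _stage2_config() -> TCEDConfig:
    # noisy target (stage-1 residual): keep spatial dropout so the fit does
    # not memorize the primary channel's own noise, and use a deeper pyramid
    # whose receptive field spans more than one fetal RR interval so the
    # denoiser can exploit beat-to-beat quasi-periodicity
    return TCEDConfig(feature_channels=[8, 16, 32, 64], dilation_rates=[1, 2, 4, 8],
                      learning_rate=3e-3, dropout_rate=0.1)


@dataclass
class PipelineConfig:
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    stage1_tced: TCEDConfig = field(default_factory=_stage1_config)
    stage2_tced: TCEDConfig = field(default_factory=_stage2_config)
    stage1_epochs: int = 100
    stage2_epochs: int = 200
    reference_mode: str = "thoracic_channel"   # or "synthetic"
    abdominal_channels: list = None            # None -> all role=abdominal
    primary_channels: list = None              # None -> all abdominal
    use_jade: bool = True
    fetal_hr_range: tuple = (100, 200)
    seed: int = 0


@dataclass
class ChannelOutput:
    mecg_estimate: np.ndarray
    stage1_residual: np.ndarray
    stage2_estimates: list
    fecg: np.ndarray               # final fetal signal (after JADE if enabled)
    fetal_peaks: PeakAnnotations
    fhr_times: np.ndarray
    fhr_bpm: np.ndarray
    stage1_loss: np.ndarray
    reference: np.ndarray


@dataclass
class ExtractionReport:
    channels: dict                  # abdominal channel index -> ChannelOutput
    metrics: dict                   # channel index -> dict of statistics
    seed: int
    config: PipelineConfig


def _derived_seed(master: int, *tags) -> int:
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2**31 - 1))


def run_extraction(record: ECGRecord, config: PipelineConfig = None,
                   truth_fecg: np.ndarray = None,
                   reference_peaks: PeakAnnotations = None) -> ExtractionReport:
    """Extract the fetal ECG from every requested abdominal channel.

    ``truth_fecg`` (per-abdominal-channel matrix) and ``reference_peaks``
    enable morphology metrics and SE/PPV/F1 scoring in the report.
    """
    config = config or PipelineConfig()
    fs = record.fs
    abd = config.abdominal_channels or record.channels_with_role("abdominal")
    if not abd:
        raise ValueError("record has no abdominal channels")
    primaries = config.primary_channels if config.primary_channels is not None else list(abd)

    # -- preprocessing ------------------------------------------------------
    pre = {c: preprocess_channel(record.signals[c], fs, config.filter_spec) for c in abd}
    if config.reference_mode == "thoracic_channel":
        tho = record.channels_with_role("thoracic")
        if not tho:
            raise ValueError("no thoracic channel in the record; use reference_mode='synthetic'")
        thoracic = preprocess_channel(record.signals[tho[0]], fs, config.filter_spec)
        references = {c: thoracic for c in abd}
    elif config.reference_mode == "synthetic":
        references = {c: build_synthetic_thoracic(pre[c], fs) for c in abd}
    else:
        raise ValueError(f"unknown reference mode {config.reference_mode!r}")

    # -- stage 1: maternal elimination on every abdominal channel -----------
    stage1 = {}
    for c in abd:
        seed1 = _derived_seed(config.seed, 1, c)
        logger.info("stage=1 channel=%d epochs=%d seed=%d", c, config.stage1_epochs, seed1)
        stage1[c] = eliminate_mecg(pre[c], references[c], config=config.stage1_tced,
                                   epochs=config.stage1_epochs, seed=seed1)

    residuals = {c: stage1[c].residual for c in abd}
    single_channel = len(abd) < 2
    if single_channel:
        warnings.warn("single abdominal channel: stage-2 denoising skipped, "
                      "stage-1 residual returned", stacklevel=2)

    channels, metrics = {}, {}
    for c in primaries:
        if single_channel:
            estimates, final = [], residuals[c]
        else:
            seed2 = _derived_seed(config.seed, 2, c)
            logger.info("stage=2 primary=%d epochs=%d seed=%d", c, config.stage2_epochs, seed2)
            order = [c] + [o for o in abd if o != c]
            dn = denoise_fecg([residuals[o] for o in order], 0,
                              config=config.stage2_tced, epochs=config.stage2_epochs, seed=seed2)
            estimates = dn.estimates
            stacked = np.vstack(estimates)
            if config.use_jade and len(estimates) >= 2:
                try:
                    bss = jade_separate(stacked)
                    final = select_fetal_component(bss, stacked.mean(axis=0))
                except Exception as exc:  # degenerate estimate sets fall back
                    logger.warning("JADE skipped on channel %d: %s", c, exc)
                    final = stacked.mean(axis=0)
            else:
                final = stacked.mean(axis=0)

        peaks = detect_r_peaks(final, fs, hr_range_bpm=config.fetal_hr_range)
        t_fhr, bpm = fhr_trace(peaks)
        channels[c] = ChannelOutput(
            mecg_estimate=stage1[c].estimate, stage1_residual=residuals[c],
            stage2_estimates=estimates, fecg=final, fetal_peaks=peaks,
            fhr_times=t_fhr, fhr_bpm=bpm, stage1_loss=stage1[c].loss_trace,
            reference=references[c])

        m = {"n_detected_peaks": int(len(peaks))}
        if reference_peaks is not None:
            pm = match_peaks(peaks, reference_peaks)
            m.update(TP=pm.TP, FP=pm.FP, FN=pm.FN, SE=pm.SE, PPV=pm.PPV, F1=pm.F1)
        if truth_fecg is not None:
            row = abd.index(c)
            truth = preprocess_channel(np.asarray(truth_fecg)[row], fs, config.filter_spec)
            mm = morphology_metrics(truth, final, align=True)
            m.update(MSE=mm.MSE, SNR=mm.SNR, R=mm.R)
            mm1 = morphology_metrics(truth, residuals[c], align=True)
            m.update(stage1_MSE=mm1.MSE, stage1_SNR=mm1.SNR, stage1_R=mm1.R)
        metrics[c] = m

    return ExtractionReport(channels=channels, metrics=metrics, seed=config.seed, config=config)
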