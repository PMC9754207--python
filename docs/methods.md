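# Methods

## Signal model and scope

The package treats a multichannel abdominal recording as the additive
mixture `AECG = MECG + FECG + n` per channel, with the abdominal maternal
component a nonlinear transform `f(TECG)` of the maternal chest signal.
The goal is a fetal waveform whose *morphology* survives extraction, not
only its QRS positions.  Three stages: (1) online nonlinear ANC against a
thoracic (or synthetic) reference to remove the maternal component,
(2) online cross-channel ANC to denoise the fetal residuals, (3) JADE to
fuse the stage-2 estimate set into one clean component.

## Preprocessing

Band-pass 0.5-100 Hz, then per-channel z-scoring.  The filter is a
4th-order Butterworth applied forward-backward: zero phase, because group
delay would distort the very morphology the method is meant to preserve.
The 0.5 Hz edge removes baseline wander while keeping fetal T-waves; the
100 Hz edge removes high-frequency content.  Records are reflect-padded by
3 s before filtering to suppress edge transients.  The filter family,
order and direction are package choices (only the cutoffs are inherent to
the method); all are config-exposed.  Powerline interference is left to
the networks rather than notched out.

## TCED-Net

A 1-D U-Net-style encoder-decoder over dilated *causal* convolutions
(`y(n) = sum_i f(i) x(n - d i)`, left-only zero padding of `(k-1)d`).
Full-scale configuration: six levels, feature channels
[16, 32, 64, 128, 256, 512], dilation rates [1, 2, 4, 8, 16, 16], kernel
size 5, average pooling stride 2 between encoder levels, transposed
convolution (kernel 2, stride 2) in the decoder, skip concatenation
between mirrored levels, final 1x1 projection.  Each level is a residual
temporal block: two stacked [dilated conv -> batch norm -> SELU -> spatial
dropout] layers plus the block input through a 1x1 convolution when the
channel counts differ.

Implementation notes:

- Forward pass, analytic backpropagation and Adam (0.9/0.999) are written
  directly on numpy arrays; gradients are verified against central finite
  differences in the test suite.
- Normalization always uses current-record statistics.  The network is fit
  online on the very record it predicts (batch = the whole signal), so
  there is no separate inference distribution; only dropout distinguishes
  training from evaluation mode.
- Initialization is LeCun normal (variance-preserving under SELU) with
  zero biases; together with SELU(0) = 0 this makes an all-zero input
  propagate to an exactly zero output, which the tests assert.
- Inputs are right-padded with zeros to a multiple of 2^(levels-1) and the
  output trimmed, so any record length is accepted.
- Transposed-convolution kernel 2/stride 2 doubles length exactly with no
  overlap artifacts; pooling halves only the length, never the channel
  count (the channel plan follows the per-level feature list).

## Online ANC fitting

`fit_online` minimizes whole-record MSE between the network output (fed
the reference) and the target signal.  Both signals are standardized
internally and the estimate mapped back to target units, so conditioning
does not depend on the residuals' scale; the additive identity
`estimate + residual = target` is exact by construction.  The loss trace
records training-mode MSE per epoch; the reported estimate is an
evaluation-mode pass, and `final_loss` is its MSE.

Because fetal signal and noise are uncorrelated with the thoracic
reference, the stage-1 error decomposes as
`eps = E[(M - y)^2] + E[F^2] + E[n^2]`: the fit can approach but not fall
below the fetal-plus-noise power (the "ANC floor"), and the minimizer's
output is the abdominal maternal component.  The observable regression
target is the abdominal ECG itself — the "maternal ground truth" is
unobservable and enters only through this expectation argument.  Stage 2
swaps the roles: the primary channel's *fetal* component is what the
reference channels share, so the network output (not the residual) is the
fetal estimate, and a fresh network (fresh seeded initialization) is fit
per reference channel.

Epoch defaults are 100 (stage 1) and 200 (stage 2): the thoracic
reference is high-SNR and fits quickly, while the noisy stage-2 targets
converge more slowly; large epoch counts risk memorizing the primary
channel's own noise, which would correlate the estimate errors across
references and defeat the later fusion.  An optional early-stop (patience
20, relative tolerance 1e-4) is available but off by default.

## Desk-scale configuration

All shipped defaults, tests and the acceptance script run a reduced
network sized for one CPU and minute-long records at 250 Hz:

- stage 1: three levels [8, 16, 32], dilations [1, 2, 4], kernel 5,
  learning rate 1e-2, no dropout.  The reference is high-SNR, so the fit
  is driven to the ANC floor as fast as possible; at reduced capacity the
  step size is raised accordingly (the full-scale network uses 1e-3).
- stage 2: four levels [8, 16, 32, 64], dilations [1, 2, 4, 8], learning
  rate 3e-3, spatial dropout 0.1.  The extra level extends the receptive
  field beyond one fetal RR interval, letting the denoiser exploit
  beat-to-beat quasi-periodicity; dropout guards against memorizing the
  primary channel's noise.

The full-scale configuration remains the `TCEDConfig()` default and is
what a GPU reproduction on the public databases would use.

## Synthetic thoracic reference

For recordings without a chest lead, maternal R peaks are detected on the
abdominal channel itself (the maternal QRS dominates), windows of
+/-0.35 s around each peak are averaged into a template (0.7 s spans P
through T at term maternal rates), and the template is overlap-added at
every detected peak over a zero baseline.  Overlapping placements simply
add; fewer than 3 detected beats is an error.

## JADE and component selection

Whitening by eigendecomposition of the covariance, a maximal set of
fourth-order cumulant matrices, joint diagonalization by Givens sweeps
(stop when no rotation exceeds 1e-8, cap 100 sweeps).  Rank-deficient
covariance raises a degenerate-input error (the pipeline falls back to
the estimate mean).  BSS leaves permutation/sign/scale free, so the final
component is chosen by maximum |Pearson correlation| with the mean of the
stage-2 estimates and affinely re-fit to it by least squares.  JADE runs
per primary channel on that channel's estimate set.

## Peak detection and scoring

Energy-based QRS detection: band-pass 5-40 Hz (zero phase), derivative,
squaring, 80 ms moving-window integration, candidate peaks at a refractory
spacing of 60/HR_max seconds, adaptive threshold at one quarter of the
90th-percentile candidate height, refinement to the local extremum of the
filtered signal.  The maternal/fetal distinction enters only through the
heart-rate range ((50, 120) vs (100, 200) bpm).

Beat matching solves a rectangular assignment problem: maximize the
number of detected/reference pairs within |dt| <= 50 ms, then minimize
total |dt|; each peak is used at most once.  (A nearest-first greedy
pairing is not cardinality-optimal — e.g. reference {0, 60}, detections
{50, 100} at a 50-sample window — so the optimal assignment is used and
checked against an exhaustive dynamic-programming oracle in the tests.)
Empty denominators define SE/PPV/F1 as 0.  Morphology metrics (MSE,
SNR = 10 log10(sum x^2 / sum (x - xhat)^2) capped at 100 dB, Pearson R)
optionally re-fit the extraction affinely to the truth first, removing the
BSS amplitude ambiguity.  The fetal heart-rate trace is 60/RR at matched
beats, median-filtered over 5 beats.

## The simulator

`simulate_recording` emulates the study conditions rather than any
database's exact noise spectra:

- Maternal and fetal trains are five-Gaussian (P, Q, R, S, T) cycle
  templates concatenated with per-beat RR drawn from a truncated normal;
  defaults: maternal 82 +/- 2 bpm, fetal 140 +/- 4 bpm.
- Each abdominal channel applies its own thoracic-to-abdominal transform:
  random short FIR (leading unit tap), gain U(0.7, 1.4), smooth tanh
  saturation (strength U(0.2, 0.6); identity at 0), latency 0-5 samples —
  emulating electrode-placement diversity.  The fetal train enters each
  channel with its own gain and small latency, scaled so the median fetal
  |R| is 0.2 of the median maternal |R| on that channel.
- Noise mixes baseline wander (Gaussian noise low-passed below 0.5 Hz),
  powerline (50 Hz sinusoid, random phase) and broadband Gaussian at
  weights 0.3/0.2/0.5, scaled per channel to exact total power
  `P_fetal / 10^(dB/10)`; 0 dB (noise as strong as the fetal signal) is
  the reference condition.  Noise is drawn independently per channel.
- The additive identity `signals = truth_mecg + truth_fecg + truth_noise`
  holds exactly, and the returned peak trains are the generators' own.
- One master seed drives independent substreams, so changing the noise
  configuration does not move beat times.

What the simulator does *not* model: fetal movement and vernix effects,
waveform variability beyond Gaussian templates, electrode pops/motion
artifacts, multiple pregnancies, and the specific colored-noise spectra
of recorded EMG.  Passing tests therefore demonstrate the machinery and
its statistical behavior under the stated mixture model, not clinical
performance; the benchmark CLI exists to run the identical pipeline on
real WFDB data locally.

## Numerical and degenerate-input choices

- z-scoring a constant signal returns zeros with a warning (flat leads
  happen); a zero-variance ground truth makes R undefined and raises,
  while a zero-variance extraction yields R = NaN with a warning so the
  forced `SNR = 0 dB` case remains computable.
- WFDB output uses 16-bit encoding with per-channel gain spanning the
  signal range (round-trip error at most one ADC step); CSV round-trips
  bit-exactly.  Sample indexing is 0-based everywhere; 1-based annotation
  files must be declared on read.
- Non-finite training loss raises a divergence error naming the epoch.
- Single-channel records skip stage 2 with a warning and return the
  stage-1 residual.

## Known limitations

- The desk-scale network cannot match full-scale morphology numbers; at
  0 dB the per-channel stage-1 residual correlation is bounded near
  sqrt(P_F / (P_F + P_n)) ~ 0.71, and stage 2 + JADE lifts the final
  correlation to ~0.8-0.87 on the reference simulation.
- The synthetic thoracic reference degrades when fetal and maternal QRS
  overlap heavily, as the template averaging absorbs fetal energy.
- Converged weights are record-specific by design; no transfer across
  records is attempted.
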