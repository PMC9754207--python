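import numpy as np
import pytest

from fetanc.anc import (InsufficientBeatsError, NotEnoughReferencesError,
                        build_synthetic_thoracic, denoise_fecg, eliminate_mecg, fit_online)
from fetanc.preprocess import bandpass_filter, preprocess_channel, zscore_normalize
from fetanc.simulate import MATERNAL_TEMPLATE, gaussian_ecg_cycle, synthesize_ecg_train
from fetanc.tced import TCEDConfig

FAST = TCEDConfig(feature_channels=[4, 8], dilation_rates=[1, 2], kernel_size=3,
                  dropout_rate=0.0, learning_rate=1e-2)


@pytest.fixture(scope="module")
def ecg_5s():
    sig, _ = synthesize_ecg_train(MATERNAL_TEMPLATE, 82, 2, 200, 5, seed=4)
    return zscore_normalize(sig)


class TestFitOnline:
    def test_exact_decomposition(self, ecg_5s, rng):
        target = ecg_5s + 0.1 * rng.standard_normal(ecg_5s.size)
        _, res = fit_online(ecg_5s, target, FAST, epochs=5, seed=0)
        np.testing.assert_array_equal(res.residual, target - res.estimate)

    def test_identity_task_learnable(self, ecg_5s):
        _, res = fit_online(ecg_5s, ecg_5s, FAST, epochs=60, seed=0)
        assert res.final_loss < 0.05 * ecg_5s.var()
        assert res.loss_trace[-1] <= res.loss_trace[0]

    def test_uncorrelated_target_floor(self, ecg_5s, rng):
        noise = rng.standard_normal(ecg_5s.size)
        _, res = fit_online(ecg_5s, noise, FAST, epochs=60, seed=0)
        assert res.final_loss >= 0.8 * noise.var()

    def test_seeded_reproducibility(self, ecg_5s):
        _, a = fit_online(ecg_5s, ecg_5s, FAST, epochs=3, seed=9)
        _, b = fit_online(ecg_5s, ecg_5s, FAST, epochs=3, seed=9)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)
        np.testing.assert_array_equal(a.estimate, b.estimate)

    def test_length_mismatch_rejected(self, ecg_5s):
        with pytest.raises(ValueError):
            fit_online(ecg_5s, ecg_5s[:-5], FAST, epochs=1)

    def test_early_stop_plateaus(self, ecg_5s):
        _, res = fit_online(ecg_5s, ecg_5s, FAST, epochs=500, seed=0,
                            early_stop=True, patience=5, rel_tol=0.5)
        assert res.epochs_run < 500
        assert len(res.loss_trace) == res.epochs_run


class TestEliminateMecg:
    def test_degenerate_reference_equals_target(self, ecg_5s):
        res = eliminate_mecg(ecg_5s, ecg_5s, config=FAST, epochs=60, seed=1)
        assert np.mean(res.residual**2) < 0.05 * ecg_5s.var()

    def test_recovers_fetal_component(self, clean_sim):
        # nearly noise-free mixture: the stage-1 residual should track the
        # true fetal component closely
        rec = clean_sim.record
        fs = rec.fs
        c = clean_sim.abdominal_indices[0]
        pre = preprocess_channel(rec.signals[c], fs)
        tho = preprocess_channel(rec.signals[clean_sim.thoracic_index], fs)
        res = eliminate_mecg(pre, tho, config=TCEDConfig.reduced(
            learning_rate=1e-2, dropout_rate=0.0), epochs=100, seed=0)
        truth = bandpass_filter(clean_sim.truth_fecg[0], fs)
        r = np.corrcoef(res.residual, truth)[0, 1]
        assert r >= 0.8

    def test_estimation_error_orthogonal_to_fetal(self, clean_sim):
        # after convergence the maternal-estimation error should be nearly
        # uncorrelated with the fetal component
        rec = clean_sim.record
        fs = rec.fs
        c = clean_sim.abdominal_indices[0]
        pre = preprocess_channel(rec.signals[c], fs)
        tho = preprocess_channel(rec.signals[clean_sim.thoracic_index], fs)
        res = eliminate_mecg(pre, tho, config=TCEDConfig.reduced(
            learning_rate=1e-2, dropout_rate=0.0), epochs=100, seed=2)
        raw = bandpass_filter(rec.signals[c], fs)
        m_z = bandpass_filter(clean_sim.truth_mecg[0], fs) / raw.std()
        f_z = bandpass_filter(clean_sim.truth_fecg[0], fs)
        err = res.estimate - (m_z - m_z.mean())
        assert abs(np.corrcoef(err, f_z)[0, 1]) < 0.2

    def test_pure_maternal_cancellation(self, rng):
        # no fetal signal, no noise: residual power collapses
        sig, _ = synthesize_ecg_train(MATERNAL_TEMPLATE, 82, 2, 200, 5, seed=6)
        aecg = zscore_normalize(0.8 * sig)
        tho = zscore_normalize(sig)
        res = eliminate_mecg(aecg, tho, config=FAST, epochs=80, seed=0)
        assert np.mean(res.residual**2) < 0.1 * aecg.var()


class TestDenoise:
    def test_reference_count(self, ecg_5s, rng):
        chans = [ecg_5s + 0.2 * rng.standard_normal(ecg_5s.size) for _ in range(4)]
        dn = denoise_fecg(chans, 0, config=FAST, epochs=2, seed=0)
        assert len(dn.estimates) == 3
        assert dn.reference_indices == [1, 2, 3]

    def test_single_channel_rejected(self, ecg_5s):
        with pytest.raises(NotEnoughReferencesError):
            denoise_fecg([ecg_5s], 0, config=FAST, epochs=1)

    def test_identical_references_reproduce_primary(self, ecg_5s):
        dn = denoise_fecg([ecg_5s, ecg_5s.copy(), ecg_5s.copy()], 0,
                          config=FAST, epochs=60, seed=0)
        for est in dn.estimates:
            assert np.corrcoef(est, ecg_5s)[0, 1] > 0.97


class TestSyntheticThoracic:
    def test_template_matches_true_cycle(self):
        fs = 250
        sig, peaks = synthesize_ecg_train(MATERNAL_TEMPLATE, 80, 0, fs, 30, seed=3)
        out = build_synthetic_thoracic(sig, fs)
        # compare one beat of the output against the true maternal cycle
        p = peaks.indices[10]
        half = int(0.24 * fs)
        cyc = gaussian_ecg_cycle(MATERNAL_TEMPLATE, fs, 60 / 80)
        r_off = int(round(0.36 * cyc.size))
        truth = cyc[r_off - half: r_off + half]
        assert np.corrcoef(out[p - half: p + half], truth)[0, 1] >= 0.9

    def test_support_limited_to_peak_windows(self):
        fs = 250
        sig, peaks = synthesize_ecg_train(MATERNAL_TEMPLATE, 80, 0, fs, 20, seed=3)
        out = build_synthetic_thoracic(sig, fs)
        half = int(round(0.35 * fs))
        mask = np.zeros(sig.size, dtype=bool)
        from fetanc.metrics import detect_r_peaks
        for p in detect_r_peaks(sig, fs, (50, 120)).indices:
            mask[max(p - half, 0): p + half + 1] = True
        assert np.all(out[~mask] == 0.0)

    def test_zero_input_insufficient_beats(self):
        with pytest.raises(InsufficientBeatsError):
            build_synthetic_thoracic(np.zeros(5000), 250)
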