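"""Evoked-potential pipeline: filtering, epoching, Woody, slopes, SVR."""

import numpy as np
import pandas as pd
import pytest

from neobag import evoked as E
from neobag import synthetic as S


def _tone(freq, fs=500.0, dur=60.0):
    t = np.arange(0, dur, 1 / fs)
    return np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def _ratio(self, freq):
        rec = E.EEGRecording(channels={"Cz": _tone(freq)}, fs=500.0)
        out = E.preprocess_eeg(rec)
        mid = out.channels["Cz"][int(20 * 500):int(40 * 500)]
        return np.max(np.abs(mid))

    def test_passband_preserved(self):
        assert self._ratio(10.0) > 0.95

    def test_high_frequency_attenuated(self):
        assert self._ratio(50.0) < 0.10

    def test_dc_removed(self):
        rec = E.EEGRecording(channels={"Cz": np.full(30_000, 7.0)}, fs=500.0)
        assert np.abs(E.preprocess_eeg(rec).channels["Cz"]).max() < 0.5

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            E.preprocess_eeg(E.EEGRecording(channels={"Cz": np.zeros(500)},
                                            fs=50.0))


class TestEpoching:
    def _rec(self, x, fs, ann):
        return E.EEGRecording(channels={"Oz": x, "Cz": x}, fs=fs,
                              annotations=pd.DataFrame(ann))

    def test_constant_channel_epochs_are_zero(self):
        fs = 500.0
        rec = self._rec(np.full(int(20 * fs), 5.0), fs,
                        {"time_s": [5.0, 10.0], "modality": ["visual"] * 2})
        eps = E.epoch_and_baseline(rec)["visual"]
        assert eps.n_epochs == 2
        np.testing.assert_allclose(eps.epochs, 0.0, atol=1e-12)

    def test_baseline_means_vanish(self, rng):
        fs = 500.0
        rec = self._rec(rng.normal(size=int(30 * fs)), fs,
                        {"time_s": [5.0, 12.0, 20.0],
                         "modality": ["tactile"] * 3})
        eps = E.epoch_and_baseline(rec)["tactile"]
        pre_means = eps.epochs[:, eps.times < 0].mean(axis=1)
        np.testing.assert_allclose(pre_means, 0.0, atol=1e-9)

    def test_edge_annotation_skipped(self):
        fs = 500.0
        rec = self._rec(np.zeros(int(10 * fs)), fs,
                        {"time_s": [0.1, 5.0], "modality": ["visual"] * 2})
        eps = E.epoch_and_baseline(rec)["visual"]
        assert eps.n_epochs == 1

    def test_no_annotations_rejected(self):
        rec = E.EEGRecording(channels={"Oz": np.zeros(5000)}, fs=500.0)
        with pytest.raises(ValueError, match="annotations"):
            E.epoch_and_baseline(rec)

    def test_constant_offset_equivariance(self, basis500):
        eps, _ = S.simulate_evoked(33.0, basis500, "visual", noise_sd=2.0,
                                   jitter_ms=0.0, n_epochs=6, seed=3)
        shifted = E.EpochSet(eps.epochs + 40.0, eps.times, eps.fs, "visual")
        # re-baseline both: identical results
        base = eps.epochs - eps.epochs[:, eps.times < 0].mean(axis=1,
                                                              keepdims=True)
        base2 = shifted.epochs - shifted.epochs[:, eps.times < 0].mean(
            axis=1, keepdims=True)
        np.testing.assert_allclose(base, base2, atol=1e-9)


class TestArtifactRejection:
    def _eps(self, basis, n=8, seed=0, frac=0.0):
        eps, _ = S.simulate_evoked(33.0, basis, "visual", noise_sd=1.0,
                                   jitter_ms=0.0, n_epochs=n,
                                   artifact_fraction=frac, seed=seed)
        return eps

    def test_spike_epoch_rejected(self, basis500):
        eps = self._eps(basis500, n=10, frac=0.2, seed=1)
        out = E.reject_artifacts(eps)
        assert out.n_kept == 8
        assert out.n_epochs == 10        # never removes epochs, only flags

    def test_exactly_150uV_kept(self, basis500):
        eps = self._eps(basis500, n=1, seed=2)
        epochs = eps.epochs.copy()
        epochs[0, 10] = 150.0            # pre-stimulus sample, at the limit
        out = E.reject_artifacts(E.EpochSet(epochs, eps.times, eps.fs,
                                            "visual"))
        assert out.n_kept == 1
        epochs[0, 10] = 150.0001
        out = E.reject_artifacts(E.EpochSet(epochs, eps.times, eps.fs,
                                            "visual"))
        assert out.n_kept == 0

    def test_fewer_than_five_epochs_unavailable(self, basis500):
        eps = self._eps(basis500, n=4, seed=3)
        assert not E.sensory_available([E.reject_artifacts(eps)])
        eps5 = self._eps(basis500, n=5, seed=3)
        assert E.sensory_available([E.reject_artifacts(eps5)])


class TestWoody:
    def test_template_itself_has_zero_lag(self, basis500):
        eps, _ = S.simulate_evoked(33.0, basis500, "visual", noise_sd=0.0,
                                   jitter_ms=0.0, n_epochs=3, seed=0)
        template = E.nrf_template(eps, basis500)
        _, lags = E.woody_align(eps, template)
        np.testing.assert_array_equal(lags, 0.0)

    def test_known_shift_recovered(self, basis500):
        eps, _ = S.simulate_evoked(33.0, basis500, "visual", noise_sd=0.0,
                                   jitter_ms=0.0, n_epochs=1, seed=0)
        template = eps.epochs[0].copy()
        shift = int(0.020 * basis500.fs)          # +20 ms
        shifted = np.zeros_like(template)
        shifted[shift:] = template[:-shift]
        sh_eps = E.EpochSet(shifted[None, :], eps.times, eps.fs, "visual")
        aligned, lags = E.woody_align(sh_eps, template)
        # brute-force oracle over all admissible integer lags
        max_lag = int(round(50e-3 * basis500.fs))
        scores = [np.dot(np.roll(shifted, -k), template)
                  for k in range(-max_lag, max_lag + 1)]
        oracle = (int(np.argmax(scores)) - max_lag) / basis500.fs
        assert lags[0] == pytest.approx(oracle, abs=1.0 / basis500.fs)
        assert lags[0] == pytest.approx(0.020, abs=1.0 / basis500.fs)
        np.testing.assert_allclose(aligned.epochs[0][shift:-shift],
                                   template[shift:-shift], atol=1e-9)

    def test_large_shift_clipped_to_max_jitter(self, basis500):
        eps, _ = S.simulate_evoked(33.0, basis500, "visual", noise_sd=0.0,
                                   jitter_ms=0.0, n_epochs=1, seed=0)
        template = eps.epochs[0].copy()
        shift = int(0.080 * basis500.fs)          # +80 ms
        shifted = np.zeros_like(template)
        shifted[shift:] = template[:-shift]
        sh_eps = E.EpochSet(shifted[None, :], eps.times, eps.fs, "visual")
        _, lags = E.woody_align(sh_eps, template)
        assert abs(lags[0]) <= 0.050 + 1e-12

    def test_alignment_never_changes_epoch_count(self, basis500):
        eps, _ = S.simulate_evoked(33.0, basis500, "visual", noise_sd=2.0,
                                   jitter_ms=30.0, n_epochs=9, seed=4)
        aligned, _ = E.woody_align(eps, E.nrf_template(eps, basis500))
        assert aligned.n_epochs == 9

    def test_alignment_reduces_residual_on_jittered_epochs(self, basis500):
        eps, slopes = S.simulate_evoked(33.0, basis500, "visual",
                                        noise_sd=0.5, jitter_ms=40.0,
                                        n_epochs=30, seed=5)
        clean = basis500.for_modality("visual").T @ slopes[:4]

        def residual(e):
            fitted = E.fit_nrf_slopes(e, None, basis500)[:4]
            return np.linalg.norm(e.average()
                                  - basis500.for_modality("visual").T @ fitted)

        aligned, _ = E.woody_align(eps, clean)
        assert residual(aligned) <= residual(eps) + 1e-12


class TestSlopes:
    def test_orthonormal_projection_is_exact(self, basis500):
        avg = (2.0 * basis500.waveforms[0])
        eps = E.EpochSet(np.tile(avg, (6, 1)), basis500.times, basis500.fs,
                         "visual")
        tac = E.EpochSet(np.zeros((5, len(basis500.times))), basis500.times,
                         basis500.fs, "tactile")
        slopes = E.fit_nrf_slopes(eps, tac, basis500)
        np.testing.assert_allclose(slopes, [2, 0, 0, 0, 0, 0], atol=1e-10)

    def test_noisy_two_component_recovery(self, basis500, rng):
        truth = 1.0 * basis500.waveforms[0] + 3.0 * basis500.waveforms[1]
        epochs = truth + 0.01 * rng.standard_normal((20, len(basis500.times)))
        eps = E.EpochSet(epochs, basis500.times, basis500.fs, "visual")
        slopes = E.fit_nrf_slopes(eps, None, basis500)
        assert abs(slopes[0] - 1.0) < 0.05 and abs(slopes[1] - 3.0) < 0.05

    def test_zero_response_gives_zero_slopes(self, basis500):
        eps = E.EpochSet(np.zeros((5, len(basis500.times))), basis500.times,
                         basis500.fs, "visual")
        np.testing.assert_allclose(E.fit_nrf_slopes(eps, None, basis500)[:4],
                                   0.0)

    def test_rank_deficient_design_rejected(self, basis500):
        bad = E.NRFBasis(times=basis500.times,
                         waveforms=np.vstack([basis500.waveforms[:1]] * 6),
                         n_visual=4, n_tactile=2, fs=basis500.fs)
        eps = E.EpochSet(np.zeros((5, len(basis500.times))), basis500.times,
                         basis500.fs, "visual")
        with pytest.raises(np.linalg.LinAlgError):
            E.fit_nrf_slopes(eps, None, bad)


class TestSensoryModel:
    def _cohort_slopes(self, n=60, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(31, 36.9, n)
        slopes = S.default_slope_age_map(ages)
        slopes = slopes + noise * rng.standard_normal(slopes.shape)
        return slopes, ages

    def test_cross_validated_mae_below_one_week(self):
        slopes, ages = self._cohort_slopes()
        model = E.train_sensory_model(slopes, ages, seed=0)
        assert model.cv_mae_weeks <= 1.0

    def test_noise_free_limit(self):
        slopes, ages = self._cohort_slopes(noise=0.0)
        model = E.train_sensory_model(slopes, ages, seed=0)
        assert model.cv_mae_weeks < 0.2

    def test_permuted_ages_match_null_model(self):
        slopes, ages = self._cohort_slopes(seed=1)
        rng = np.random.default_rng(2)
        model = E.train_sensory_model(slopes, rng.permutation(ages), seed=0)
        null_mae = np.mean(np.abs(ages - ages.mean()))
        assert model.cv_mae_weeks > 0.7 * null_mae

    def test_degenerate_ages_rejected(self):
        slopes, ages = self._cohort_slopes()
        with pytest.raises(ValueError):
            E.train_sensory_model(slopes, np.full_like(ages, 34.0), seed=0)

    def test_prediction_deterministic_and_finite(self):
        slopes, ages = self._cohort_slopes()
        model = E.train_sensory_model(slopes, ages, seed=0)
        p1 = E.predict_sensory_age(model, slopes[:5])
        p2 = E.predict_sensory_age(model, slopes[:5])
        np.testing.assert_array_equal(p1, p2)
        assert np.all(np.isfinite(p1))

    def test_untrained_model_rejected(self):
        with pytest.raises(RuntimeError):
            E.predict_sensory_age(E.SensoryAgeModel(), np.zeros(6))
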