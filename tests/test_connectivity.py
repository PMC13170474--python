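"""Cross-spectra, PLV, wPLI, gating and the whole-brain index."""

import numpy as np
import pytest

from doceeg import bands, connectivity, preprocess, synthetic
from doceeg.connectivity import (
    ConnectivityMatrix,
    gate_by_plv,
    global_wpli,
    plv_matrix,
    windowed_fourier,
    wpli_matrix,
)
from doceeg.errors import ConfigurationError, EmptyDataError, InvalidInputError
from doceeg.recording import EEGRecording


def _epochs(data, fs=250.0):
    return preprocess.epoch(EEGRecording(data, fs=fs))


class TestWindowedFourier:
    def test_onbin_sinusoid_concentrates_energy(self):
        t = np.arange(15000) / 250.0
        cs = windowed_fourier(_epochs(np.tile(np.sin(2 * np.pi * 10 * t), (2, 1))))
        power = np.abs(cs.coeffs[0, 0]) ** 2
        assert cs.freqs[np.argmax(power)] == pytest.approx(10.0)
        assert power.max() / power.sum() > 0.95 / 2  # energy split over +/- lobe bins

    def test_bin_resolution_half_hz(self):
        cs = windowed_fourier(_epochs(np.zeros((2, 15000)) + 1.0))
        assert cs.freqs[1] - cs.freqs[0] == pytest.approx(0.5)

    def test_dc_only_signal(self):
        # the Hann taper itself occupies bins 0 and +/-1; beyond that, nothing
        cs = windowed_fourier(_epochs(np.full((2, 15000), 3.0)))
        assert np.abs(cs.coeffs[:, :, 2:]).max() < 1e-9

    def test_parseval_identity(self, rng):
        eps = _epochs(rng.standard_normal((2, 15000)))
        cs = windowed_fourier(eps)
        n = eps.epochs.shape[2]
        win = np.hanning(n + 1)[:-1]  # periodic hann, as used by the estimator
        tapered = eps.epochs * win
        time_energy = (tapered[0, 0] ** 2).sum()
        spec = cs.coeffs[0, 0]
        spec_energy = (np.abs(spec[0]) ** 2 + 2 * (np.abs(spec[1:-1]) ** 2).sum()
                       + np.abs(spec[-1]) ** 2) / n
        assert spec_energy == pytest.approx(time_energy, rel=1e-6)

    def test_empty_epochs_rejected(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 15000)), fs=250.0)
        eps = preprocess.epoch(rec, keep_mask=np.zeros(59, dtype=bool))
        with pytest.raises(EmptyDataError):
            windowed_fourier(eps)


class TestPLV:
    def test_identical_channels_plv_one(self, rng):
        x = rng.standard_normal(15000)
        cs = windowed_fourier(_epochs(np.vstack([x, x])))
        assert plv_matrix(cs, bands.ALPHA).values[0, 1] == pytest.approx(1.0)

    def test_fixed_lag_plv_one(self, lagged_alpha_pair):
        cs = windowed_fourier(preprocess.epoch(lagged_alpha_pair))
        assert plv_matrix(cs, bands.ALPHA).values[0, 1] > 0.99

    def test_null_plv_near_epoch_scaling(self, noise_pair):
        cs = windowed_fourier(preprocess.epoch(noise_pair))
        val = plv_matrix(cs, bands.ALPHA).values[0, 1]
        assert 0.03 < val < 0.3  # concentrated near 1/sqrt(59) ~ 0.13

    def test_long_recording_null_below_gate(self):
        rec = EEGRecording(
            np.random.default_rng(5).standard_normal((2, 60000)), fs=250.0)
        cs = windowed_fourier(preprocess.epoch(rec))
        assert plv_matrix(cs, bands.ALPHA).values[0, 1] < 0.1

    def test_band_without_bins_rejected(self, noise_pair):
        cs = windowed_fourier(preprocess.epoch(noise_pair))
        with pytest.raises(ConfigurationError):
            plv_matrix(cs, bands.BandDefinition("sub", 0.05, 0.2))


class TestWPLI:
    def test_quarter_cycle_lag_wpli_one(self, lagged_alpha_pair):
        cs = windowed_fourier(preprocess.epoch(lagged_alpha_pair))
        assert wpli_matrix(cs, bands.ALPHA).values[0, 1] == pytest.approx(1.0)

    def test_zero_lag_single_source_exactly_zero(self, rng):
        x = rng.standard_normal(15000)
        cs = windowed_fourier(_epochs(np.vstack([x, 0.3 * x])))
        assert wpli_matrix(cs, bands.ALPHA).values[0, 1] == 0.0

    def test_null_wpli_at_floor_59_epochs(self):
        # non-debiased wPLI null ~ 2/sqrt(pi E): ~0.15 at 59 epochs
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            cs = windowed_fourier(_epochs(r.standard_normal((2, 15000))))
            vals.append(wpli_matrix(cs, bands.ALPHA).values[0, 1])
        assert 0.08 < np.mean(vals) < 0.25

    def test_null_wpli_decays_with_epochs(self):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            cs = windowed_fourier(_epochs(r.standard_normal((2, 60000))))
            vals.append(wpli_matrix(cs, bands.ALPHA).values[0, 1])
        assert np.mean(vals) < 0.1  # 239 epochs

    def test_volume_conduction_mixture_stays_at_null_floor(self):
        # zero-lag leakage raises PLV but adds no consistent imaginary part
        plvs, wplis = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            rec = EEGRecording(r.standard_normal((2, 15000)), fs=250.0)
            mixed = synthetic.mix_volume_conduction(rec, 0.5)
            cs = windowed_fourier(preprocess.epoch(mixed))
            plvs.append(plv_matrix(cs, bands.ALPHA).values[0, 1])
            wplis.append(wpli_matrix(cs, bands.ALPHA).values[0, 1])
        assert np.mean(plvs) > 0.1
        assert np.mean(wplis) < 0.25
        assert np.mean(wplis) < np.mean(plvs) / 2

    def test_rescaling_invariance(self, rng):
        data = rng.standard_normal((3, 15000))
        cs1 = windowed_fourier(_epochs(data))
        cs2 = windowed_fourier(_epochs(data * np.array([[2.0], [0.5], [7.0]])))
        for band in (bands.ALPHA, bands.GAMMA):
            np.testing.assert_allclose(wpli_matrix(cs1, band).values,
                                       wpli_matrix(cs2, band).values, atol=1e-9)
            np.testing.assert_allclose(plv_matrix(cs1, band).values,
                                       plv_matrix(cs2, band).values, atol=1e-9)

    def test_matches_naive_pair_loop_oracle(self, rng):
        data = rng.standard_normal((4, 5000))
        eps = _epochs(data)
        cs = windowed_fourier(eps)
        band = bands.BETA
        fast = wpli_matrix(cs, band).values
        sel = np.flatnonzero(band.mask(cs.freqs))
        slow = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                per_bin = []
                for f in sel:
                    im = np.imag(cs.coeffs[:, i, f] * np.conj(cs.coeffs[:, j, f]))
                    den = np.abs(im).sum()
                    per_bin.append(abs(im.sum()) / den if den > 0 else 0.0)
                slow[i, j] = np.mean(per_bin)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_bounds_symmetry_zero_diag(self, rng):
        cs = windowed_fourier(_epochs(rng.standard_normal((5, 15000))))
        for band in bands.CANONICAL_BANDS:
            for mat in (wpli_matrix(cs, band), plv_matrix(cs, band)):
                v = mat.values
                assert (v >= 0).all() and (v <= 1).all()
                np.testing.assert_allclose(v, v.T)
                assert np.diag(v).max() == 0.0


class TestGateAndGlobal:
    def _mat(self, values, metric="wPLI"):
        return ConnectivityMatrix(band=bands.ALPHA, values=values, metric=metric)

    def test_full_plv_passes_everything(self):
        w = self._mat(np.array([[0, 0.4], [0.4, 0]]))
        p = self._mat(np.ones((2, 2)) - np.eye(2), metric="PLV")
        out = gate_by_plv(w, p)
        np.testing.assert_array_equal(out.values, w.values)
        assert out.gated

    def test_zero_plv_zeroes_everything(self):
        w = self._mat(np.array([[0, 0.4], [0.4, 0]]))
        p = self._mat(np.zeros((2, 2)), metric="PLV")
        assert gate_by_plv(w, p).values.max() == 0.0

    def test_mixed_gate_elementwise_oracle(self, rng):
        n = 6
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        p = rng.random((n, n)) * 0.2
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0)
        out = gate_by_plv(self._mat(w), self._mat(p, metric="PLV"), 0.1)
        np.testing.assert_array_equal(out.values, np.where(p > 0.1, w, 0.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            gate_by_plv(self._mat(np.zeros((2, 2))),
                        self._mat(np.zeros((3, 3)), metric="PLV"))

    def test_global_mean_of_constant_matrix(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0)
        assert global_wpli(self._mat(v)) == pytest.approx(0.3)

    def test_global_three_pairs(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.2
        v[0, 2] = v[2, 0] = 0.4
        v[1, 2] = v[2, 1] = 0.6
        assert global_wpli(self._mat(v)) == pytest.approx(0.4)

    def test_global_equals_pair_enumeration(self, rng):
        n = 7
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        pairs = [v[i, j] for i in range(n) for j in range(i + 1, n)]
        assert global_wpli(self._mat(v)) == pytest.approx(np.mean(pairs))


class TestBandProfile:
    def test_awake_gamma_dominates(self, profiles):
        wins = 0
        for seed in range(6):
            rec = synthetic.generate_eeg(profiles["awake"], n_channels=8,
                                         duration=60, fs=250, seed=seed)
            prof = connectivity.band_profile(preprocess.epoch(rec))
            wins += max(prof, key=prof.get) == "gamma"
        assert wins >= 5

    def test_anesthesia_slow_band_dominates(self, profiles):
        wins = 0
        for seed in range(6):
            rec = synthetic.generate_eeg(profiles["propofol_maintenance"],
                                         n_channels=8, duration=60, fs=250,
                                         seed=seed)
            prof = connectivity.band_profile(preprocess.epoch(rec))
            wins += max(prof, key=prof.get) in ("delta", "theta")
        assert wins >= 5
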