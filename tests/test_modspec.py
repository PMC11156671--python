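"""Modulogram transform: oracles, symmetries, localization, batching."""

import logging

import numpy as np
import pytest
from dataclasses import replace

import vocalstm as v
from vocalstm import DataError, PairingError, ParameterError
from vocalstm.modspec import modulation_power
from vocalstm.synth import Vocalization

from conftest import autocorr_dft_power


def _voc(x, rate=16000.0, speaker="s", category="song"):
    return Vocalization(samples=np.asarray(x, dtype=float), rate=rate,
                        speaker_id=speaker, category=category)


class TestMatchPairDurations:
    def test_longer_member_truncated_to_first_seconds(self):
        rate = 1000.0
        speech = _voc(np.arange(15000), rate, "a", "speech")
        song = _voc(np.arange(12000), rate, "a", "song")
        s2, sp2 = v.match_pair_durations(song, speech)
        assert s2.duration_s == sp2.duration_s == 12.0
        np.testing.assert_array_equal(sp2.samples, speech.samples[:12000])
        np.testing.assert_array_equal(s2.samples, song.samples)

    def test_equal_durations_unchanged(self):
        a = _voc(np.ones(1000), 1000.0, "a", "song")
        b = _voc(np.ones(1000), 1000.0, "a", "speech")
        a2, b2 = v.match_pair_durations(a, b)
        assert len(a2.samples) == len(b2.samples) == 1000

    def test_pairing_errors(self):
        a = _voc(np.ones(10), 10.0, "a", "song")
        with pytest.raises(PairingError):
            v.match_pair_durations(a, _voc(np.ones(10), 10.0, "b", "speech"))
        with pytest.raises(PairingError):
            v.match_pair_durations(a, _voc(np.ones(10), 10.0, "a", "song"))
        with pytest.raises(DataError):
            v.match_pair_durations(a, _voc(np.empty(0), 10.0, "a", "speech"))


class TestComputeSpectrogram:
    def test_pure_tone_localized(self, grid):
        t = np.arange(int(16000 * 2)) / 16000
        s = v.compute_spectrogram(_voc(np.sin(2 * np.pi * 1000 * t)), grid)
        peak_freq = s.freqs[np.argmax(s.values.mean(axis=0))]
        assert abs(peak_freq - 1000) <= s.freqs[1] - s.freqs[0]

    def test_silence_hits_log_floor(self):
        grid = replace(v.analysis_grid(), amplitude="log")
        s = v.compute_spectrogram(_voc(np.zeros(16000)), grid)
        assert np.all(s.values == grid.log_floor_db)

    def test_white_noise_flat_in_linear_mode(self, grid):
        rng = np.random.default_rng(0)
        s = v.compute_spectrogram(_voc(rng.standard_normal(16000 * 5)), grid)
        col_means = s.values.mean(axis=0)
        assert col_means.std() / col_means.mean() < 0.2

    def test_too_short_input_rejected(self, grid):
        with pytest.raises(DataError):
            v.compute_spectrogram(_voc(np.ones(100)), grid)


class TestModulationPower:
    def test_agrees_with_autocorrelation_oracle(self):
        """Wiener-Khinchin: |2D DFT|^2 of the mean-removed spectrogram equals
        the 2D DFT of its explicit autocorrelation (5 random cases)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.standard_normal((rng.integers(9, 20), rng.integers(8, 16)))
            oracle, _ = autocorr_dft_power(x)
            nt, nf = x.shape
            power, _, _ = modulation_power(x, 0.01, 15.0, n_t_fft=2 * nt - 1, n_f_fft=2 * nf - 1)
            impl = np.fft.ifftshift(power)
            err = np.linalg.norm(impl - oracle) / np.linalg.norm(oracle)
            assert err < 1e-6

    def test_parseval_total_power_equals_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 17))
        for pad in (None, (64, 64)):
            kw = {} if pad is None else {"n_t_fft": pad[0], "n_f_fft": pad[1]}
            power, _, _ = modulation_power(x, 0.01, 15.0, **kw)
            assert power.sum() == pytest.approx(x.var(), rel=1e-9)

    def test_hermitian_point_symmetry(self):
        """A real spectrogram's 2D power spectrum satisfies
        P(-t, -s) = P(t, s)."""
        rng = np.random.default_rng(2)
        power, _, _ = modulation_power(rng.standard_normal((21, 15)), 0.01, 15.0)
        flipped = power[::-1, ::-1]
        # with odd sizes fftshift centres DC, so a full flip maps onto itself
        np.testing.assert_allclose(power, flipped, rtol=1e-10, atol=1e-12)

    def test_truncating_fft_sizes_rejected(self):
        with pytest.raises(ParameterError):
            modulation_power(np.ones((10, 10)), 0.01, 15.0, n_t_fft=5)


class TestComputeModulogram:
    def test_scaling_covariance(self, grid):
        voc = v.synth_ripple(v.RippleSpec(2.0, 3.0), 3.0, 16000)
        s = v.compute_spectrogram(voc, grid)
        m1 = v.compute_modulogram(s, grid)
        s2 = replace(s, values=3.0 * s.values)
        m2 = v.compute_modulogram(s2, grid)
        np.testing.assert_allclose(m2.power, 9.0 * m1.power, rtol=1e-8)

    def test_axes_and_nonnegativity(self, grid, small_stm):
        m = v.compute_modulogram(
            v.compute_spectrogram(v.synth_ripple(v.RippleSpec(1.0, 2.0), 2.5, 16000), grid), grid
        )
        assert np.all(m.power >= 0)
        assert np.all(np.diff(m.spectral_axis) > 0) and m.spectral_axis[0] == 0
        assert np.all(np.diff(m.temporal_axis) > 0)
        assert 0 in m.temporal_axis
        np.testing.assert_allclose(m.temporal_axis, -m.temporal_axis[::-1])

    @pytest.mark.parametrize("spectral", [1.0, 3.5, 6.0])
    @pytest.mark.parametrize("temporal", [-6.0, 0.7, 4.0])
    def test_ripple_localization_within_one_grid_step(self, grid, spectral, temporal):
        voc = v.synth_ripple(v.RippleSpec(spectral, temporal, depth=0.9), 4.0, 16000)
        m = v.compute_modulogram(v.compute_spectrogram(voc, grid), grid)
        s_hat, t_hat = m.argmax_coords()
        assert abs(s_hat - spectral) <= grid.spec_step + 1e-9
        assert abs(t_hat - temporal) <= grid.temp_step + 1e-9

    def test_temporal_resolution_improves_with_duration(self, grid):
        """Longer signals concentrate a ripple's energy more tightly around
        its temporal modulation frequency."""
        spreads = []
        for dur in (2.0, 4.0, 8.0):
            voc = v.synth_ripple(v.RippleSpec(2.0, 4.0), dur, 16000)
            m = v.compute_modulogram(v.compute_spectrogram(voc, grid), grid)
            marginal = m.power.sum(axis=0)
            marginal = marginal / marginal.sum()
            spreads.append(np.sqrt(np.sum(marginal * (m.temporal_axis - 4.0) ** 2)))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_nyquist_violations_rejected(self):
        with pytest.raises(ParameterError):
            v.StmGrid(temp_max=60.0)  # hop-limited temporal Nyquist is 50 Hz
        grid = v.StmGrid(spec_max=40.0)  # beyond the spectral Nyquist at 16 kHz
        voc = v.synth_ripple(v.RippleSpec(1.0, 2.0), 2.0, 16000)
        s = v.compute_spectrogram(voc, grid)
        with pytest.raises(ParameterError):
            v.compute_modulogram(s, grid)


class TestBatchStm:
    def test_row_counts_and_order_invariance(self, small_corpus, grid, small_stm):
        _, corpus = small_corpus
        assert small_stm.X.shape[0] == len(corpus)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(corpus))
        shuffled = v.batch_stm([corpus[i] for i in perm], grid)
        key = lambda stm: stm.meta["speaker_id"] + "_" + stm.meta["category"]
        lookup = {k: i for i, k in enumerate(key(shuffled))}
        reordered = shuffled.X[[lookup[k] for k in key(small_stm)]]
        np.testing.assert_array_equal(small_stm.X, reordered)

    def test_rerun_bit_identical(self, small_corpus, grid, small_stm):
        _, corpus = small_corpus
        again = v.batch_stm(corpus, grid)
        np.testing.assert_array_equal(small_stm.X, again.X)

    def test_unpaired_speaker_skipped_with_warning(self, small_corpus, grid, caplog):
        _, corpus = small_corpus
        broken = corpus[1:]  # drop one song -> its speaker is unpaired
        with caplog.at_level(logging.WARNING, logger="vocalstm.modspec"):
            stm = v.batch_stm(broken, grid)
        assert stm.X.shape[0] == len(corpus) - 2
        assert any("pair" in rec.message for rec in caplog.records)

    def test_hdf5_roundtrip(self, small_stm, tmp_path):
        import h5py

        with h5py.File(tmp_path / "stm.h5", "w") as f:
            small_stm.to_hdf5(f.create_group("stm"))
        with h5py.File(tmp_path / "stm.h5") as f:
            back = v.STMDataset.from_hdf5(f["stm"])
        np.testing.assert_array_equal(back.X, small_stm.X)
        assert list(back.meta["speaker_id"]) == list(small_stm.meta["speaker_id"])
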