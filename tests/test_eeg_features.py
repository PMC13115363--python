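"""Differential-entropy feature pipeline: filters, DE, baseline, grid."""

import math

import numpy as np
import pytest
from scipy import integrate, signal as sps

from msdafuse import eeg_features as ef
from msdafuse.eeg_features import (DEFAULT_BANDS, EEGTrial, bandpass,
                                   baseline_de, correct_baseline,
                                   de_window_matrix, differential_entropy,
                                   extract_samples, map_to_grid,
                                   window_segments)

FS = 128.0


def gaussian_de_quadrature(sigma2: float) -> float:
    """Oracle: -integral of f*ln(f) for a Gaussian density (natural log)."""
    sd = math.sqrt(sigma2)

    def integrand(x):
        f = math.exp(-x * x / (2 * sigma2)) / (sd * math.sqrt(2 * math.pi))
        return -f * math.log(f) if f > 0 else 0.0

    val, _ = integrate.quad(integrand, -12 * sd, 12 * sd, limit=200)
    return val


class TestDifferentialEntropy:
    @pytest.mark.parametrize("sigma2", [0.1, 1.0, 10.0])
    def test_closed_form_matches_quadrature(self, sigma2, rng):
        # fix the sample variance of the window to sigma2 exactly
        w = rng.standard_normal(64)
        w = (w - w.mean()) / w.std(ddof=1) * math.sqrt(sigma2)
        de = differential_entropy(w)
        assert de == pytest.approx(gaussian_de_quadrature(sigma2), rel=1e-6)

    def test_unit_variance_value(self, rng):
        w = rng.standard_normal(256)
        w = (w - w.mean()) / w.std(ddof=1)
        assert differential_entropy(w) == pytest.approx(1.4189, abs=1e-3)

    def test_zero_point_variance(self, rng):
        w = rng.standard_normal(64)
        target = 1.0 / (2 * math.pi * math.e)
        w = (w - w.mean()) / w.std(ddof=1) * math.sqrt(target)
        assert differential_entropy(w) == pytest.approx(0.0, abs=1e-12)

    def test_scaling_adds_log_of_factor(self, rng):
        w = rng.standard_normal(64)
        for c in (2.0, 0.5, 10.0):
            assert differential_entropy(c * w) == pytest.approx(
                differential_entropy(w) + math.log(c), rel=1e-12)

    def test_strictly_increasing_in_variance(self, rng):
        w = rng.standard_normal(64)
        des = [differential_entropy(w * s) for s in (0.5, 1.0, 2.0, 5.0)]
        assert all(a < b for a, b in zip(des, des[1:]))

    def test_constant_window_floored_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert differential_entropy(np.ones(64)) == ef.DE_FLOOR

    def test_configurable_log_base(self, rng):
        w = rng.standard_normal(64)
        assert differential_entropy(w, log_base=2.0) == pytest.approx(
            differential_entropy(w) / math.log(2.0), rel=1e-12)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(0, 10, 1 / FS)
        tone = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass(tone, DEFAULT_BANDS[1], FS)  # alpha 8-13 Hz
        assert np.sqrt((out ** 2).mean()) >= 0.9 * np.sqrt((tone ** 2).mean())

    def test_stopband_tone_rejected(self):
        t = np.arange(0, 10, 1 / FS)
        tone = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass(tone, DEFAULT_BANDS[3], FS)  # gamma 31-45 Hz
        assert np.sqrt((out ** 2).mean()) <= 0.05 * np.sqrt((tone ** 2).mean())

    def test_white_noise_band_power_matches_periodogram_oracle(self, rng):
        x = rng.standard_normal(int(FS * 120))
        freqs, pxx = sps.periodogram(x, fs=FS)
        total = pxx.sum()
        for band in DEFAULT_BANDS:
            out = bandpass(x, band, FS)
            measured = (out ** 2).sum() / (x ** 2).sum()
            oracle = pxx[(freqs >= band.low) & (freqs <= band.high)].sum() / total
            assert measured == pytest.approx(oracle, rel=0.10)

    def test_band_above_nyquist_rejected(self):
        band = ef.BandDefinition("bad", 50.0, 70.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(256), band, FS)


class TestWindowing:
    def test_deap_task_span_gives_120_windows_of_64(self, rng):
        x = rng.standard_normal(int(FS * 60))
        wins = window_segments(x, FS, 0.5)
        assert len(wins) == 120
        assert all(w.shape == (64,) for w in wins)
        # partition: concatenation reproduces the signal
        np.testing.assert_array_equal(np.concatenate(wins), x)

    @pytest.mark.parametrize("seconds,n", [(0.5, 1), (0.4, 0), (1.2, 2)])
    def test_window_counts(self, seconds, n, rng):
        x = rng.standard_normal(int(FS * seconds))
        if n == 0:
            with pytest.warns(UserWarning):
                assert window_segments(x, FS, 0.5) == []
        else:
            assert len(window_segments(x, FS, 0.5)) == n

    def test_fractional_sample_window_rejected(self):
        with pytest.raises(ValueError, match="whole"):
            window_segments(np.zeros(100), 128.0, 0.3)


class TestBaseline:
    def test_shape_and_mean_of_six_windows(self, rng):
        prep = rng.standard_normal((32, int(FS * 3)))
        base = baseline_de(prep, DEFAULT_BANDS, FS)
        assert base.shape == (32, 4)
        filtered = np.stack([bandpass(prep, b, FS) for b in DEFAULT_BANDS])
        per_window = de_window_matrix(filtered, FS)
        assert per_window.shape[0] == 6
        np.testing.assert_allclose(base, per_window.mean(axis=0))

    def test_stationary_signal_baseline_close_to_single_window(self, rng):
        prep = rng.standard_normal((4, int(FS * 3)))
        base = baseline_de(prep, DEFAULT_BANDS, FS)
        filtered = np.stack([bandpass(prep, b, FS) for b in DEFAULT_BANDS])
        single = de_window_matrix(filtered, FS)[0]
        np.testing.assert_allclose(base, single, atol=0.5)

    def test_wrong_prep_span_rejected_unless_relaxed(self, rng):
        prep = rng.standard_normal((2, int(FS * 2)))
        with pytest.raises(ValueError, match="preparation span"):
            baseline_de(prep, DEFAULT_BANDS, FS)
        assert baseline_de(prep, DEFAULT_BANDS, FS, strict=False).shape == (2, 4)

    def test_correct_baseline_identity_neutral_linear(self, rng):
        task = rng.standard_normal((120, 32, 4))
        base = rng.standard_normal((32, 4))
        np.testing.assert_array_equal(correct_baseline(task, np.zeros((32, 4))), task)
        np.testing.assert_allclose(correct_baseline(base[None], base), 0.0)
        shift = rng.standard_normal((120, 32, 4))
        np.testing.assert_allclose(correct_baseline(task + shift, base),
                                   correct_baseline(task, base) + shift)
        with pytest.raises(ValueError, match="mismatch"):
            correct_baseline(task, np.zeros((5, 4)))


class TestGridMapping:
    def test_zero_vector_maps_to_zero_grid(self, deap_layout):
        assert map_to_grid(np.zeros(32), deap_layout).sum() == 0.0

    def test_conservation_and_zero_cell_count(self, deap_layout, rng):
        v = rng.standard_normal(32)
        grid = map_to_grid(v, deap_layout)
        assert grid.shape == (8, 9)
        assert grid.sum() == pytest.approx(v.sum(), rel=1e-12)
        # oracle: enumerate layout occupancy
        occupied = {(r, c) for _, r, c in deap_layout.entries}
        assert (grid == 0).sum() >= 72 - len(occupied)
        assert np.count_nonzero(grid) <= len(occupied)
        # exactly 40 cells are structurally zero for the 32-channel layout
        assert 72 - len(occupied) == 40

    def test_length_mismatch_rejected(self, deap_layout):
        with pytest.raises(ValueError, match="channels"):
            map_to_grid(np.zeros(30), deap_layout)


@pytest.fixture(scope="module")
def deap_trial():
    rng = np.random.default_rng(777)
    x = rng.standard_normal((32, int(FS * 63)))
    # boost beta band on channel 5 during the task span
    t = np.arange(int(FS * 63)) / FS
    beta_tone = np.sin(2 * np.pi * 20.0 * t) * (t >= 3.0)
    x[5] += 4.0 * beta_tone
    return EEGTrial(samples=x)


class TestExtractSamples:
    def test_deap_trial_yields_20_samples_of_1728_dims(self, deap_trial, deap_layout):
        samples = extract_samples(deap_trial, deap_layout, label=1)
        assert len(samples) == 20
        for s in samples:
            assert s.tensor.shape == (6, 4, 8, 9)
            assert s.tensor.reshape(-1).size == 1728
            assert s.label == 1

    def test_window_grouping_is_an_ordered_partition(self, deap_trial, deap_layout):
        samples = extract_samples(deap_trial, deap_layout)
        spans = [s.step_span for s in samples]
        assert spans[0][0] == 0
        assert all(b[0] == a[1] + 1 for a, b in zip(spans, spans[1:]))
        assert spans[-1][1] == 119

    def test_non_electrode_cells_zero_everywhere(self, deap_trial, deap_layout):
        samples = extract_samples(deap_trial, deap_layout)
        empty = ~deap_layout.occupancy()
        for s in samples:
            assert np.all(s.tensor[:, :, empty] == 0.0)

    def test_elevated_beta_channel_dominates_its_grid_cell(self, deap_trial,
                                                           deap_layout):
        samples = extract_samples(deap_trial, deap_layout)
        beta = np.stack([s.tensor for s in samples])[:, :, 2]  # beta band
        mean_map = beta.mean(axis=(0, 1))
        r, c = deap_layout.positions()[5]
        assert mean_map[r, c] == mean_map.max()
        assert mean_map[r, c] > 0

    def test_pipeline_is_deterministic(self, deap_trial, deap_layout):
        a = extract_samples(deap_trial, deap_layout)
        b = extract_samples(deap_trial, deap_layout)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.tensor, s2.tensor)

    def test_channel_count_mismatch_rejected(self, deap_layout, rng):
        trial = EEGTrial(samples=rng.standard_normal((30, int(FS * 63))),
                         channel_names=None)
        with pytest.raises(ValueError, match="channels"):
            extract_samples(trial, deap_layout)
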