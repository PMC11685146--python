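"""Synthetic MI-EEG generator: layout, determinism, spectral contract."""

import numpy as np
import pytest

from mifeatlab import EffectSpec, generate_dataset

from .oracles import periodogram_band_power

BANDS = {"delta": (0.5, 4), "theta": (4, 8), "alpha": (8, 13),
         "beta": (13, 30), "gamma": (30, 100)}


class TestLayout:
    def test_default_dimensions_and_balance(self, small_dataset):
        ds = small_dataset
        assert ds.data.shape == (16, 22, 750)
        assert ds.fs == 250.0
        counts = np.bincount(ds.labels)[1:]
        assert counts.tolist() == [4, 4, 4, 4]

    def test_four_trial_labels_are_balanced_multiset(self):
        ds = generate_dataset(1, 4, [], seed=0)
        assert sorted(ds.labels.tolist()) == [1, 2, 3, 4]

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            generate_dataset(1, 10, [], seed=0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_dataset(2, 8, [], seed=42)
        b = generate_dataset(2, 8, [], seed=42)
        assert a.data.tobytes() == b.data.tobytes()
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        a = generate_dataset(1, 8, [], seed=1)
        b = generate_dataset(1, 8, [], seed=2)
        assert not np.array_equal(a.data, b.data)


class TestEffectValidation:
    def test_band_above_nyquist_names_effect(self):
        eff = EffectSpec(1, (3,), (100.0, 130.0), 2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_dataset(1, 8, [eff], seed=0)

    def test_invalid_class_names_effect(self):
        eff = EffectSpec(9, (3,), (8.0, 13.0), 2.0)
        with pytest.raises(ValueError, match="class_id"):
            generate_dataset(1, 8, [eff], seed=0)

    def test_nonpositive_power_ratio_rejected(self):
        with pytest.raises(ValueError, match="power_ratio"):
            EffectSpec(1, (3,), (8.0, 13.0), 0.0)


class TestSpectralContent:
    def test_power_ratio_recovered_by_periodogram(self, effect_dataset):
        """Injected 4x alpha power on channel 8 lands in [2, 8] vs class 2."""
        ds = effect_dataset
        p1 = periodogram_band_power(ds.data[ds.labels == 1], 8, (8, 13), ds.fs)
        p2 = periodogram_band_power(ds.data[ds.labels == 2], 8, (8, 13), ds.fs)
        assert 2.0 <= p1 / p2 <= 8.0

    def test_unaffected_channel_shows_no_effect(self, effect_dataset):
        ds = effect_dataset
        p1 = periodogram_band_power(ds.data[ds.labels == 1], 5, (8, 13), ds.fs)
        p2 = periodogram_band_power(ds.data[ds.labels == 2], 5, (8, 13), ds.fs)
        assert 0.7 <= p1 / p2 <= 1.4

    def test_null_generator_has_no_spurious_band_signal(self):
        """Without effects, class-mean band powers agree within 3 SE."""
        ds = generate_dataset(1, 288, [], seed=23)
        from scipy.signal import periodogram

        f, pxx = periodogram(ds.data[:, 7, :], fs=ds.fs, axis=-1)
        for lo, hi in BANDS.values():
            band = pxx[:, (f >= lo) & (f < hi)].mean(axis=1)
            g1 = band[ds.labels == 1]
            g2 = band[ds.labels == 2]
            se = np.sqrt(g1.var(ddof=1) / g1.size + g2.var(ddof=1) / g2.size)
            assert abs(g1.mean() - g2.mean()) < 3 * se

    def test_band_limiting_and_notch(self):
        """Spectrum is empty outside 0.5-100 Hz and at the 50 Hz mains bin."""
        ds = generate_dataset(1, 8, [], seed=3)
        y = np.abs(np.fft.rfft(ds.data[0, 0]))
        f = np.fft.rfftfreq(750, 1 / 250)
        assert y[(f < 0.4) | (f > 100.5)].max() < 1e-9 * y.max()
        assert y[np.abs(f - 50) < f[1] / 2].max() < 1e-9 * y.max()
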