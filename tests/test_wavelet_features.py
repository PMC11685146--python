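"""Wavelet-packet battery W1..W15: Parseval, node ordering, pywt oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mifeatlab import DEFAULT_BANDS, node_band_table, wavelet_band_features, wpt_decompose
from mifeatlab.features.wavelet import wavelet_feature_table, wpt_table

from .oracles import pywt_packet_nodes, wavelet_oracle

FS = 250.0
N = 750


class TestDecomposition:
    def test_terminal_node_count_and_width(self):
        dec = wpt_decompose(np.ones(N), FS)
        assert dec.n_nodes == 128
        assert dec.node_width_hz == pytest.approx(0.9765625)
        assert dec.node_edges[0, 0] == 0.0
        assert dec.node_edges[-1, 1] == pytest.approx(125.0)

    def test_constant_series_concentrates_in_dc_node(self):
        dec = wpt_decompose(np.full(1024, 3.0), FS)
        e = dec.node_energies()
        assert e[0] == pytest.approx(1024 * 9.0)
        assert np.all(e[1:] == 0)

    def test_impulse_of_length_128_one_coefficient_per_node(self):
        x = np.zeros(128)
        x[0] = 1.0
        dec = wpt_decompose(x, FS)
        assert dec.nodes.shape == (128, 1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="128"):
            wpt_decompose(np.ones(100), FS)

    @given(st.integers(0, 10_000))
    def test_parseval_total_node_energy_equals_signal_energy(self, seed):
        x = np.random.default_rng(seed).standard_normal(N)
        dec = wpt_decompose(x, FS)
        np.testing.assert_allclose(dec.node_energies().sum(), np.sum(x**2),
                                   rtol=1e-9)

    def test_coefficients_match_pywt_freq_order_exactly(self, rng):
        """Vectorized butterflies + Gray reorder == pywt periodization/freq."""
        X = rng.standard_normal((4, N))
        mine = wpt_table(X)
        for i in range(4):
            np.testing.assert_allclose(mine[i], pywt_packet_nodes(X[i]),
                                       rtol=1e-12, atol=1e-12)


class TestBandAssignment:
    def test_nodes_partition_the_passband(self):
        table = node_band_table(FS)
        all_nodes = np.concatenate(list(table.values()))
        assert len(all_nodes) == len(set(all_nodes.tolist()))
        # every node whose midpoint lies in [0.5, 100) is assigned
        width = FS / 2 / 128
        mids = (np.arange(128) + 0.5) * width
        expected = np.flatnonzero((mids >= 0.5) & (mids < 100))
        assert sorted(all_nodes.tolist()) == expected.tolist()

    def test_band_narrower_than_node_cites_resolution(self):
        with pytest.raises(ValueError, match="0.9766"):
            node_band_table(FS, bands={"sliver": (10.0, 10.5)})


class TestBandFeatures:
    def test_zero_signal_all_zero_with_zero_log_zero_convention(self):
        feats = wavelet_band_features(wpt_decompose(np.zeros(N), FS))
        assert np.all(feats == 0)

    def test_oracle_equivalence_on_seeded_series(self):
        rng = np.random.default_rng(303)
        X = rng.standard_normal((30, N))
        got = wavelet_feature_table(X, FS)
        want = np.array([wavelet_oracle(row, FS, DEFAULT_BANDS) for row in X])
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_table_equals_per_series_path(self, rng):
        X = rng.standard_normal((3, N))
        table = wavelet_feature_table(X, FS)
        rows = np.stack([wavelet_band_features(wpt_decompose(r, FS)) for r in X])
        np.testing.assert_allclose(table, rows, rtol=1e-12)

    @given(st.floats(0.1, 10.0), st.integers(0, 10_000))
    def test_band_energy_scales_squared(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(N)
        base = wavelet_band_features(wpt_decompose(x, FS))[0::3]
        scaled = wavelet_band_features(wpt_decompose(c * x, FS))[0::3]
        np.testing.assert_allclose(scaled, c**2 * base, rtol=1e-9)
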