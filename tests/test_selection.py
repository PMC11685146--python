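"""Feature matrix assembly, significance screening, distribution maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mifeatlab import (
    FeatureDescriptor,
    FeatureMatrix,
    build_feature_matrix,
    distribution_map,
    significance_filter,
)
from mifeatlab.selection import DOMAIN_CODES, DistributionMap

from .oracles import permutation_pvalue


def _noise_matrix(n_samples=120, n_features=40, n_classes=2, seed=0):
    """Null FeatureMatrix: i.i.d. noise columns, labels independent of data."""
    rng = np.random.default_rng(seed)
    descs = [FeatureDescriptor("T", t + 1, c + 1)
             for t in range(n_features // 2) for c in range(2)]
    return FeatureMatrix(
        values=rng.standard_normal((n_samples, n_features)),
        descriptors=descs[:n_features],
        labels=np.tile(np.arange(1, n_classes + 1), n_samples // n_classes),
        subjects=np.ones(n_samples, int),
    )


class TestBuildFeatureMatrix:
    def test_column_counts_per_domain(self, small_dataset):
        for domains, expected in [(("T",), 528), (("F",), 330),
                                  (("W",), 330), (("P",), 176)]:
            fm = build_feature_matrix(small_dataset, domains)
            assert fm.n_features == expected

    def test_column_order_domain_major_type_then_channel(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("T", "P"))
        names = fm.column_names
        assert names[:3] == ["T1_ch1", "T1_ch2", "T1_ch3"]
        assert names[22] == "T2_ch1"
        assert names[528] == "P1_ch1"
        assert names[-1] == "P8_ch22"

    def test_single_channel_poincare_block(self):
        from mifeatlab import EpochedTrials

        rng = np.random.default_rng(0)
        t = EpochedTrials(rng.standard_normal((4, 1, 64)), np.array([1, 1, 2, 2]),
                          np.ones(4, int), fs=250.0)
        fm = build_feature_matrix(t, ("P",))
        assert fm.n_features == 8

    def test_empty_domain_set_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            build_feature_matrix(small_dataset, ())

    def test_values_independent_of_chunking(self, small_dataset):
        a = build_feature_matrix(small_dataset, ("T", "F"), chunk_trials=4)
        b = build_feature_matrix(small_dataset, ("T", "F"), chunk_trials=1000)
        np.testing.assert_array_equal(a.values, b.values)


class TestSignificanceFilter:
    def test_identical_groups_give_p_one(self):
        fm = _noise_matrix(n_samples=6, n_features=2)
        fm.values[:, 0] = [1, 1, 2, 2, 3, 3]  # (1,2,3) vs (1,2,3)
        sel = significance_filter(fm)
        assert sel.method == "t-test"
        assert sel.p_values[0] == pytest.approx(1.0)
        assert not sel.mask[0]

    def test_four_identical_groups_give_p_one(self):
        fm = _noise_matrix(n_samples=80, n_features=4, n_classes=4, seed=1)
        base = np.random.default_rng(1).standard_normal(20)
        for c in (1, 2, 3, 4):  # same multiset per class: means equal, F = 0
            fm.values[fm.labels == c, 0] = base
        sel = significance_filter(fm)
        assert sel.method == "ANOVA"
        assert sel.p_values[0] > 0.99

    def test_zero_variance_column_p_one_with_warning(self, caplog):
        fm = _noise_matrix()
        fm.values[:, 3] = 7.0
        with caplog.at_level("WARNING"):
            sel = significance_filter(fm)
        assert sel.p_values[3] == 1.0
        assert "zero-variance" in caplog.text

    def test_tiny_class_rejected(self):
        fm = _noise_matrix(n_samples=10)
        fm.labels = np.array([1] * 9 + [2])
        with pytest.raises(ValueError, match="class 2"):
            significance_filter(fm)

    def test_null_selection_rate_in_binomial_band(self):
        fm = _noise_matrix(n_samples=200, n_features=200, seed=7)
        sel = significance_filter(fm, 0.05)
        assert 0.01 <= sel.mask.mean() <= 0.12

    def test_pvalues_agree_with_permutation_oracle(self):
        fm = _noise_matrix(n_samples=60, n_features=4, seed=3)
        sel = significance_filter(fm)
        for j in range(4):
            p_perm = permutation_pvalue(fm.values[:, j], fm.labels,
                                        n_perm=2000, seed=j)
            assert abs(p_perm - sel.p_values[j]) < 0.05

    @given(st.integers(0, 1000))
    def test_mask_monotone_in_alpha(self, seed):
        fm = _noise_matrix(seed=seed)
        lo = significance_filter(fm, 0.01).mask
        hi = significance_filter(fm, 0.10).mask
        assert np.all(hi[lo])  # strict alpha mask nests


class TestDistributionMap:
    def test_empty_mask_all_false(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("P",))
        sel = significance_filter(fm)
        sel.mask[:] = False
        dm = distribution_map(sel, fm, "P")
        assert dm.grand_total == 0
        assert not dm.grid.any()

    def test_constructed_mask_row_total(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("T",))
        sel = significance_filter(fm)
        sel.mask[:] = False
        for j, d in enumerate(fm.descriptors):
            if d.code == "T3":
                sel.mask[j] = True
        dm = distribution_map(sel, fm, "T")
        assert dm.row_totals[2] == 22  # T3 row
        assert dm.grand_total == 22

    def test_map_conservation_over_domains(self, small_dataset):
        fm = build_feature_matrix(small_dataset)
        sel = significance_filter(fm)
        totals = sum(distribution_map(sel, fm, d).grand_total
                     for d in ("T", "F", "W", "P"))
        assert totals == sel.n_selected

    def test_margins_consistent(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("F",))
        dm = distribution_map(significance_filter(fm), fm, "F")
        assert dm.grand_total == dm.row_totals.sum() == dm.column_totals.sum()

    def test_csv_round_trip(self, small_dataset, tmp_path):
        fm = build_feature_matrix(small_dataset, ("F",))
        dm = distribution_map(significance_filter(fm), fm, "F")
        dm.to_csv(tmp_path / "map.csv")
        back = DistributionMap.from_csv(tmp_path / "map.csv")
        assert np.array_equal(back.grid, dm.grid)
        assert back.grand_total == dm.grand_total

    def test_text_rendering_has_marks_and_totals(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("P",))
        sel = significance_filter(fm)
        sel.mask[0] = True  # P1_ch1
        text = distribution_map(sel, fm, "P").render_text()
        assert "✓" in text
        assert text.splitlines()[0].startswith("F")

    def test_absent_domain_rejected(self, small_dataset):
        fm = build_feature_matrix(small_dataset, ("P",))
        with pytest.raises(ValueError, match="'T'"):
            distribution_map(significance_filter(fm), fm, "T")


class TestChannelRecovery:
    def test_injected_channels_dominate_frequency_map(self, effect_dataset):
        """An alpha effect on channels 8 and 12 shows up in their column totals."""
        fm = build_feature_matrix(effect_dataset, ("F",))
        dm = distribution_map(significance_filter(fm), fm, "F")
        median = np.median(dm.column_totals)
        assert dm.column_totals[7] > median
        assert dm.column_totals[11] > median
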