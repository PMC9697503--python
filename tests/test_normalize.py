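"""TPM normalization, filtering, averaging and derived per-gene scalings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phagedyn import normalize
from phagedyn.matrices import Unit, ValidationError, check_tpm_sums

from conftest import make_abundance, make_annotation, make_counts


S1 = [(0.0, 1)]


class TestRemoveBiotype:
    def test_drops_matching_genes_preserving_order(self, simple_annotation):
        cm = make_counts(
            [[1], [2], [3], [4], [5]], ["hostA", "hostB", "hostR", "hostN", "phg1"], S1,
            lengths=[500, 1000, 1500, 300, 800],
        )
        out = normalize.remove_biotype(cm, simple_annotation, "rRNA")
        assert out.genes == ["hostA", "hostB", "hostN", "phg1"]

    def test_absent_biotype_is_identity(self, simple_annotation):
        cm = make_counts([[1], [2]], ["hostA", "hostB"], S1, lengths=[500, 1000])
        out = normalize.remove_biotype(cm, simple_annotation, "tRNA")
        pd.testing.assert_frame_equal(out.data, cm.data)

    def test_removing_small_rrna_share_shrinks_total_accordingly(self, simple_annotation):
        # rRNA carries 0.6% of this sample's reads; removal drops the total by 0.6%
        total = 100_000
        rrna = int(round(0.006 * total))
        cm = make_counts(
            [[total - rrna], [rrna]], ["hostA", "hostR"], S1, lengths=[500, 1500]
        )
        out = normalize.remove_biotype(cm, simple_annotation, "rRNA")
        assert int(out.data.sum().sum()) == total - rrna
        assert out.data.sum().sum() / cm.data.sum().sum() == pytest.approx(0.994)


class TestTpmNormalize:
    def test_equal_counts_equal_lengths_split_evenly(self):
        cm = make_counts([[10], [10]], ["a", "b"], S1, lengths=[700, 700])
        tpm = normalize.tpm_normalize(cm)
        assert tpm.data[(0.0, 1)].tolist() == [500_000.0, 500_000.0]

    def test_single_gene_takes_the_whole_million(self):
        cm = make_counts([[42]], ["a"], S1, lengths=[123])
        tpm = normalize.tpm_normalize(cm)
        assert tpm.data.iloc[0, 0] == pytest.approx(1_000_000.0)

    def test_length_weighting_hand_computed(self):
        # counts 10/10, lengths 500/1000 nt -> rates 20/10 -> TPM 2/3 and 1/3
        cm = make_counts([[10], [10]], ["a", "b"], S1, lengths=[500, 1000])
        tpm = normalize.tpm_normalize(cm)
        assert tpm.data.iloc[0, 0] == pytest.approx(666_666.666667, rel=1e-9)
        assert tpm.data.iloc[1, 0] == pytest.approx(333_333.333333, rel=1e-9)

    def test_all_zero_column_warns_and_stays_zero(self):
        cm = make_counts([[0, 5]], ["a"], [(0.0, 1), (1.0, 1)], lengths=[100])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = normalize.tpm_normalize(cm)
        assert tpm.data[(0.0, 1)].tolist() == [0.0]

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 10_000), min_size=2, max_size=2), min_size=2, max_size=8
        ),
        scale=st.integers(2, 50),
    )
    def test_column_sums_and_depth_invariance(self, counts, scale):
        arr = np.asarray(counts)
        genes = [f"g{i}" for i in range(len(counts))]
        lengths = [100 + 37 * i for i in range(len(counts))]
        cm = make_counts(arr, genes, [(0.0, 1), (7.0, 1)], lengths=lengths)
        if (arr.sum(axis=0) == 0).any():
            return  # degenerate columns covered elsewhere
        tpm = normalize.tpm_normalize(cm)
        check_tpm_sums(tpm)
        scaled = normalize.tpm_normalize(make_counts(arr * scale, genes, [(0.0, 1), (7.0, 1)], lengths=lengths))
        assert np.allclose(tpm.data.to_numpy(), scaled.data.to_numpy(), rtol=1e-9)


class TestFilterLowCounts:
    def _pair(self, counts, genes, samples, lengths):
        cm = make_counts(counts, genes, samples, lengths=lengths)
        return cm, normalize.tpm_normalize(cm)

    def test_mean_below_threshold_removed(self):
        cm, tpm = self._pair([[1, 1, 1], [9, 9, 9]], ["low", "hi"], [(0.0, 1), (0.0, 2), (0.0, 3)], [100, 100])
        out, removed = normalize.filter_low_counts(cm, tpm)
        assert removed == ["low"]
        assert out.genes == ["hi"]

    @pytest.mark.parametrize(
        "counts, expect_removed",
        [((2, 2, 0), True), ((3, 2, 0), False)],  # means 4/3 and 5/3 vs 1.5
    )
    def test_threshold_boundary_arithmetic(self, counts, expect_removed):
        cm, tpm = self._pair(
            [list(counts), [50, 50, 50]], ["g", "hi"], [(0.0, 1), (0.0, 2), (0.0, 3)], [100, 100]
        )
        _out, removed = normalize.filter_low_counts(cm, tpm)
        assert ("g" in removed) is expect_removed

    def test_zero_threshold_keeps_everything(self):
        cm, tpm = self._pair([[0, 0], [1, 1]], ["a", "b"], [(0.0, 1), (1.0, 1)], [100, 100])
        out, removed = normalize.filter_low_counts(cm, tpm, threshold=0)
        assert removed == [] and out.genes == ["a", "b"]

    def test_idempotent(self):
        cm, tpm = self._pair([[1, 1], [9, 9]], ["a", "b"], [(0.0, 1), (1.0, 1)], [100, 100])
        once, removed1 = normalize.filter_low_counts(cm, tpm)
        keep = [g for g in cm.genes if g not in removed1]
        cm2 = make_counts(cm.data.loc[keep].to_numpy(), keep, [(0.0, 1), (1.0, 1)], lengths=[100] * len(keep))
        twice, removed2 = normalize.filter_low_counts(cm2, once)
        assert removed2 == []
        pd.testing.assert_frame_equal(twice.data, once.data)


class TestMeanOverReplicates:
    def test_arithmetic_mean(self):
        m = make_abundance([[10, 20, 30]], ["g"], [(4.0, 1), (4.0, 2), (4.0, 3)])
        out = normalize.mean_over_replicates(m)
        assert out.data.loc["g", 4.0] == 20.0

    def test_single_replicate_identity(self):
        m = make_abundance([[5.0, 7.0]], ["g"], [(0.0, 1), (4.0, 1)])
        out = normalize.mean_over_replicates(m)
        assert out.data.loc["g"].tolist() == [5.0, 7.0]

    def test_lfq_not_detected_counts_as_zero(self):
        m = make_abundance(
            [[np.nan, np.nan, 9.0]], ["g"], [(4.0, 1), (4.0, 2), (4.0, 3)], unit=Unit.LFQ
        )
        out = normalize.mean_over_replicates(m)
        assert out.data.loc["g", 4.0] == pytest.approx(3.0)

    def test_lfq_all_not_detected_stays_not_detected(self):
        m = make_abundance(
            [[np.nan, np.nan, 5.0, 6.0]], ["g"], [(4.0, 1), (4.0, 2), (7.0, 1), (7.0, 2)], unit=Unit.LFQ
        )
        out = normalize.mean_over_replicates(m)
        assert np.isnan(out.data.loc["g", 4.0]) and out.data.loc["g", 7.0] == 5.5


class TestZscore:
    def test_two_point_profile_gives_plus_minus_one(self):
        m = make_abundance([[0.0, 10.0]], ["g"], [0.0, 7.0])
        z = normalize.zscore_by_gene(m)
        assert z.data.loc["g"].tolist() == [-1.0, 1.0]

    def test_constant_profile_maps_to_zeros(self):
        m = make_abundance([[5.0, 5.0, 5.0]], ["g"], [0.0, 4.0, 7.0])
        z = normalize.zscore_by_gene(m)
        assert z.data.loc["g"].tolist() == [0.0, 0.0, 0.0]

    @given(st.lists(st.floats(0, 1e5, allow_nan=False), min_size=3, max_size=6))
    def test_output_standardized(self, values):
        if len(set(values)) < 2:
            return
        m = make_abundance([values], ["g"], list(range(len(values))))
        z = normalize.zscore_by_gene(m).data.loc["g"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-9)


class TestFractionOfMaxAndPercentOfT0:
    def test_fraction_of_max(self):
        m = make_abundance([[5.0, 50.0, 100.0]], ["g"], [0.0, 4.0, 7.0])
        out = normalize.fraction_of_max(m)
        assert out.data.loc["g"].tolist() == [0.05, 0.5, 1.0]

    def test_all_zero_profile_stays_zero(self):
        m = make_abundance([[0.0, 0.0]], ["g"], [0.0, 7.0])
        assert normalize.fraction_of_max(m).data.loc["g"].tolist() == [0.0, 0.0]

    def test_percent_of_t0_maps_baseline_to_100(self):
        m = make_abundance([[100.0, 50.0], [80.0, 80.0]], ["a", "b"], [0.0, 4.0])
        out = normalize.percent_of_t0(m)
        assert out.data[0.0].tolist() == [100.0, 100.0]
        assert out.data.loc["a", 4.0] == 50.0

    def test_zero_baseline_marked_undefined(self):
        m = make_abundance([[0.0, 5.0]], ["g"], [0.0, 4.0])
        out = normalize.percent_of_t0(m)
        assert out.data.loc["g"].isna().all()

    def test_missing_t0_is_an_error(self):
        m = make_abundance([[1.0, 2.0]], ["g"], [1.0, 4.0])
        with pytest.raises(ValidationError, match="t0"):
            normalize.percent_of_t0(m)


class TestEntityFractions:
    def test_all_host_gives_fraction_one(self, simple_annotation):
        m = make_abundance([[10.0, 10.0], [5.0, 1.0]], ["hostA", "hostB"], [0.0, 7.0])
        fr = normalize.entity_fractions(m, simple_annotation)
        assert fr["host_fraction"].tolist() == [1.0, 1.0]

    def test_hand_computed_ratio(self, simple_annotation):
        m = make_abundance([[800_000.0], [200_000.0]], ["hostA", "phg1"], [7.0])
        fr = normalize.entity_fractions(m, simple_annotation)
        assert fr.loc[7.0, "phage_fraction"] == pytest.approx(0.20)

    def test_fractions_sum_to_one(self, simple_annotation):
        m = make_abundance(
            [[3.0, 1.0], [2.0, 5.0], [7.0, 11.0]], ["hostA", "hostB", "phg1"], [0.0, 7.0]
        )
        fr = normalize.entity_fractions(m, simple_annotation)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_total_time_point_rejected(self, simple_annotation):
        m = make_abundance([[0.0, 1.0]], ["hostA"], [0.0, 7.0])
        with pytest.raises(ValidationError, match="zero total"):
            normalize.entity_fractions(m, simple_annotation)
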