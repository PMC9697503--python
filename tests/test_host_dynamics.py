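"""Host transcript stability, decay profiles and proteome summaries."""

import numpy as np
import pandas as pd
import pytest

from phagedyn import host_dynamics as hd
from phagedyn import normalize
from phagedyn.matrices import Unit, ValidationError

from conftest import make_abundance, make_annotation


ANNOTATION = make_annotation(
    [("a", "host", 100, "mRNA"), ("b", "host", 100, "mRNA"), ("c", "host", 100, "ncRNA"),
     ("p", "phage", 100, "mRNA")]
)
TIMES = [0.0, 4.0, 20.0]


class TestStabilityScreen:
    def test_abundant_and_retained_gene_is_stable(self):
        # mean 90 >= 10 TPM and 85/100 >= 0.8 at the final time
        m = make_abundance([[100.0, 85.0, 85.0]], ["a"], TIMES)
        rep = hd.find_stable_transcripts(m, ANNOTATION)
        assert bool(rep.loc["a", "stable"]) and rep.loc["a", "final_over_t0"] == 0.85

    def test_halved_gene_is_not_stable(self):
        m = make_abundance([[100.0, 90.0, 50.0]], ["a"], TIMES)
        rep = hd.find_stable_transcripts(m, ANNOTATION)
        assert not rep.loc["a", "stable"]

    def test_low_abundance_gene_is_not_stable(self):
        m = make_abundance([[5.0, 5.0, 5.0]], ["a"], TIMES)
        rep = hd.find_stable_transcripts(m, ANNOTATION)
        assert not rep.loc["a", "stable"]

    def test_zero_baseline_never_stable(self):
        m = make_abundance([[0.0, 50.0, 50.0]], ["a"], TIMES)
        rep = hd.find_stable_transcripts(m, ANNOTATION)
        assert not rep.loc["a", "stable"] and np.isnan(rep.loc["a", "final_over_t0"])

    def test_phage_genes_excluded_from_report(self):
        m = make_abundance([[100.0, 85.0, 85.0], [0.0, 10.0, 1000.0]], ["a", "p"], TIMES)
        rep = hd.find_stable_transcripts(m, ANNOTATION)
        assert "p" not in rep.index


class TestDecayProfile:
    def test_baseline_is_always_100_percent(self):
        m = make_abundance([[80.0, 40.0, 8.0]], ["a"], TIMES)
        curves = hd.decay_profile(m, ["a"])
        assert curves.unit is Unit.PERCENT_OF_T0
        assert curves.data.loc["a", 0.0] == 100.0

    def test_unknown_gene_listed_in_error(self):
        m = make_abundance([[80.0, 40.0, 8.0]], ["a"], TIMES)
        with pytest.raises(ValidationError, match="nope"):
            hd.decay_profile(m, ["nope"])

    def test_planted_exponential_decay_recovered(self, small_noisefree_scenario):
        # delayed-exponential host decay must reappear as the same closed
        # form in percent-of-baseline TPM space
        sc = small_noisefree_scenario
        cfg = sc.config
        tpm, _ = normalize.preprocess_counts(sc.rna.counts, sc.annotation)
        truth = sc.rna.truth
        decaying = truth[
            (truth["entity"] == "host") & (truth["biotype"] == "mRNA") & (~truth["stable"])
        ].index[:20]
        curves = hd.decay_profile(tpm, list(decaying))
        t = 7.0
        for gene in decaying:
            k = truth.loc[gene, "decay_rate_per_min"]
            expected = 100 * np.exp(-k * (t - cfg.host_decay_delay_min))
            assert curves.data.loc[gene, t] == pytest.approx(expected, rel=0.05)

    def test_planted_stable_gene_keeps_80_percent(self, small_noisefree_scenario):
        sc = small_noisefree_scenario
        tpm, _ = normalize.preprocess_counts(sc.rna.counts, sc.annotation)
        stable = sc.rna.truth.index[sc.rna.truth["stable"].fillna(False)]
        curves = hd.decay_profile(tpm, list(stable))
        assert (curves.data.iloc[:, -1] >= 80.0).all()


class TestProteinStability:
    annotation = make_annotation([("a", "host", 100, "mRNA"), ("b", "host", 100, "mRNA")])

    def test_constant_protein_scores_zero(self):
        m = make_abundance([[10.0, 10.0, 10.0]], ["a"], TIMES, unit=Unit.LFQ)
        stat, summary = hd.protein_stability_summary(m, self.annotation)
        assert stat["a"] == 0.0 and summary["median"] == 0.0

    def test_doubling_scores_one(self):
        m = make_abundance([[10.0, 20.0, 10.0]], ["a"], TIMES, unit=Unit.LFQ)
        stat, _ = hd.protein_stability_summary(m, self.annotation)
        assert stat["a"] == pytest.approx(1.0)

    def test_undetected_at_baseline_excluded(self):
        m = make_abundance([[np.nan, 20.0, 10.0]], ["a"], TIMES, unit=Unit.LFQ)
        stat, summary = hd.protein_stability_summary(m, self.annotation)
        assert summary["n"] == 0

    def test_synthetic_stable_host_proteome_scores_low(self, small_scenario):
        sc = small_scenario
        stat, summary = hd.protein_stability_summary(
            sc.protein.lfq, sc.protein.protein_annotation
        )
        assert summary["median"] < 0.5
        assert summary["fraction_within_twofold"] > 0.9


class TestAbundanceRatio:
    annotation = make_annotation([("x", "host", 100, "mRNA"), ("y", "host", 100, "mRNA")])

    def test_hand_computed_ratio(self):
        m = make_abundance([[65.0, 65.0, 65.0], [10.0, 10.0, 10.0]], ["x", "y"], TIMES, unit=Unit.LFQ)
        assert hd.abundance_ratio(m, "x", "y") == pytest.approx(6.5)

    def test_self_ratio_is_one(self):
        m = make_abundance([[3.0, 9.0, 6.0]], ["x"], TIMES, unit=Unit.LFQ)
        assert hd.abundance_ratio(m, "x", "x") == 1.0

    def test_all_not_detected_denominator_is_an_error(self):
        m = make_abundance(
            [[5.0, 5.0, 5.0], [np.nan, np.nan, np.nan]], ["x", "y"], TIMES, unit=Unit.LFQ
        )
        with pytest.raises(ValidationError):
            hd.abundance_ratio(m, "x", "y")

    def test_invariant_to_common_rescaling(self):
        m = make_abundance([[65.0, 13.0, 6.0], [10.0, 2.0, 1.0]], ["x", "y"], TIMES, unit=Unit.LFQ)
        r1 = hd.abundance_ratio(m, "x", "y")
        scaled = make_abundance(m.data.to_numpy() * 7.3, ["x", "y"], TIMES, unit=Unit.LFQ)
        assert hd.abundance_ratio(scaled, "x", "y") == pytest.approx(r1)


class TestDetectedCounts:
    annotation = make_annotation([("x", "host", 100, "mRNA"), ("p", "phage", 100, "mRNA")])

    def test_single_replicate_detection_counts(self):
        m = make_abundance(
            [[np.nan, 5.0, np.nan, np.nan], [1.0, 1.0, np.nan, 2.0]],
            ["x", "p"],
            [(5.0, 1), (5.0, 2), (8.0, 1), (8.0, 2)],
            unit=Unit.LFQ,
        )
        out = hd.detected_counts(m, self.annotation, {"host": 4, "phage": 2})
        host5 = out.query("entity == 'host' and time_min == 5.0").iloc[0]
        assert host5["n_detected"] == 1 and host5["coverage"] == 0.25
        host8 = out.query("entity == 'host' and time_min == 8.0").iloc[0]
        assert host8["n_detected"] == 0

    def test_counts_bounded_by_proteome_size(self, small_scenario):
        sc = small_scenario
        out = hd.detected_counts(
            sc.protein.lfq, sc.protein.protein_annotation, sc.protein.proteome_sizes
        )
        assert (out["coverage"] <= 1.0).all()

    def test_planted_phage_onsets_give_nondecreasing_counts(self, small_noisefree_scenario):
        sc = small_noisefree_scenario
        out = hd.detected_counts(
            sc.protein.lfq, sc.protein.protein_annotation, sc.protein.proteome_sizes
        )
        phage = out.query("entity == 'phage'").sort_values("time_min")
        assert (np.diff(phage["n_detected"]) >= 0).all()
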