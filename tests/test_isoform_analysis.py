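"""Variant-usage shifts, Durbin-Watson filtering, event classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ontodyn.expression_filter import make_calls
from ontodyn.io_tables import ExpressionMatrix, TranscriptModel
from ontodyn.isoform_analysis import (
    classify_splice_event,
    durbin_watson,
    dw_pvalue,
    dw_pvalues_batch,
    filter_novel_isoforms,
    variant_usage_report,
    variant_usage_test,
)
from ontodyn.synthetic_data import simulate_isoform_series


class TestDurbinWatson:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 6)
        assert durbin_watson(x) == pytest.approx(44 / 12)

    def test_linear_ramp(self):
        # centered ramp over 12 ages: numerator 11 * 1, denominator
        # 2 * (0.5^2 + 1.5^2 + ... + 5.5^2) = 143
        assert durbin_watson(np.arange(1.0, 13.0)) == pytest.approx(11 / 143)

    def test_iid_noise_expectation_near_two(self):
        rng = np.random.default_rng(0)
        d = [durbin_watson(rng.normal(size=12)) for _ in range(5000)]
        assert np.mean(d) == pytest.approx(2.0, abs=0.05)

    @given(st.floats(-100, 100), st.floats(0.01, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_and_scale_invariance(self, shift, scale):
        x = np.sin(np.linspace(0, 5, 12)) + np.linspace(0, 1, 12)
        base = durbin_watson(x)
        assert durbin_watson(scale * x + shift) == pytest.approx(base,
                                                                 rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            durbin_watson(np.ones(12))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.array([1.0, 2.0]))

    def test_bounded_zero_to_four(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            d = durbin_watson(rng.normal(size=12))
            assert 0.0 <= d <= 4.0


class TestDwPvalue:
    def test_smooth_series_significant(self):
        x = np.linspace(0, 10, 12)
        assert dw_pvalue(x, n_perm=999, seed=1) <= 0.01

    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = dw_pvalue(rng.normal(size=12), n_perm=999, seed=3)
            assert p >= 1 / 1000

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).normal(size=12)
        assert dw_pvalue(x, seed=5) == dw_pvalue(x, seed=5)

    def test_uniform_under_exchangeable_noise(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 12))
        p = dw_pvalues_batch(x, n_perm=999, seed=8)
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_batch_agrees_with_scalar_on_marginals(self):
        x = np.linspace(0, 10, 12)
        batch = dw_pvalues_batch(x[None, :], n_perm=999, seed=1)
        assert batch[0] <= 0.01

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            dw_pvalue(np.arange(12.0), n_perm=99)


class TestFilterNovelIsoforms:
    def test_two_stage_filtering(self, design):
        matrix, truth = simulate_isoform_series(20, 20, design=design,
                                                seed=9)
        calls = make_calls(matrix)
        records = filter_novel_isoforms(matrix, calls, n_perm=999, seed=10)
        passed = {r.transcript_id for r in records if r.passes_filter}
        auto = {t for t, flag in truth.isoform_autocorrelated.items()
                if flag}
        noise = {t for t, flag in truth.isoform_autocorrelated.items()
                 if not flag}
        # smooth expressed candidates are mostly retained (power is
        # limited for U-shaped profiles on a 12-point series), white
        # noise essentially never is
        assert len(passed & auto) >= 0.7 * len(auto)
        assert len(passed & noise) <= 0.2 * len(noise)

    def test_never_expressed_candidate_rejected_at_stage_one(self, design):
        # smooth but three orders of magnitude below the threshold
        series = np.exp2(np.repeat(np.linspace(-12, -9, design.n_ages),
                                   design.replicates_per_age))
        m = ExpressionMatrix(["t1"], series[None], design, "transcript")
        calls = make_calls(m)
        (rec,) = filter_novel_isoforms(m, calls, seed=0)
        assert not rec.passes_filter and np.isnan(rec.dw)

    def test_mismatched_calls_rejected(self, design):
        m1, _ = simulate_isoform_series(2, 2, design=design, seed=1)
        m2, _ = simulate_isoform_series(3, 2, design=design, seed=1)
        calls = make_calls(m2)
        with pytest.raises(ValueError, match="different features"):
            filter_novel_isoforms(m1, calls)


class TestVariantUsage:
    def test_identical_proportions_no_signal(self):
        table = np.array([[10.0, 20, 40], [30.0, 60, 120]])
        statistic, p, _ = variant_usage_test(table)
        assert statistic == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_dominance_flip_highly_significant(self):
        ages = 12
        a = np.linspace(0.9, 0.1, ages) * 500
        b = np.linspace(0.1, 0.9, ages) * 500
        statistic, p, _ = variant_usage_test(np.vstack([a, b]))
        expected = stats.chi2_contingency(np.vstack([a, b]),
                                          correction=False)
        assert statistic == pytest.approx(expected[0], rel=1e-9)
        assert p < 1e-4

    def test_all_zero_variant_reduces_to_single(self):
        table = np.vstack([np.linspace(10, 100, 12), np.zeros(12)])
        _, p, _ = variant_usage_test(table)
        assert p == 1.0

    def test_single_transcript_rejected(self):
        with pytest.raises(ValueError, match=">= 2 transcripts"):
            variant_usage_test(np.ones((1, 12)))

    def test_needs_expression_at_two_ages(self):
        table = np.zeros((2, 12))
        table[:, 0] = 5.0
        with pytest.raises(ValueError, match=">= 2 ages"):
            variant_usage_test(table)

    def test_report_flags_single_transcript_genes(self, design):
        matrix, _ = simulate_isoform_series(4, 0, design=design, seed=3)
        gene_of = {"tA00001": "gA", "tA00002": "gA",
                   "tA00003": "gB", "tA00004": "gC"}
        report = variant_usage_report(matrix, gene_of)
        assert report.loc["gA", "applicable"]
        assert not report.loc["gB", "applicable"]
        assert np.isnan(report.loc["gB", "p"])


class TestClassifySpliceEvent:
    REF = TranscriptModel("ref", "g", "chr1", "+",
                          ((100, 200), (300, 400), (500, 600)))

    def test_exon_two_skip_topology(self):
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((100, 200), (500, 600)))
        events = classify_splice_event(novel, [self.REF])
        assert [e.event_type for e in events] == ["exon_skip"]
        assert events[0].coordinates == ((300, 400),)

    def test_intron_retention_between_exons_one_and_two(self):
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((100, 400), (500, 600)))
        events = classify_splice_event(novel, [self.REF])
        assert [e.event_type for e in events] == ["intron_retention"]
        assert events[0].coordinates == ((200, 300),)

    def test_downstream_alt_start(self):
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((150, 200), (300, 400), (500, 600)))
        events = classify_splice_event(novel, [self.REF])
        assert [e.event_type for e in events] == ["alt_start"]
        assert events[0].coordinates == ((100, 150),)

    def test_strand_aware_start_vs_termination(self):
        ref_minus = TranscriptModel("ref", "g", "chr1", "-", self.REF.exons)
        novel = TranscriptModel("n", "g", "chr1", "-",
                                ((150, 200), (300, 400), (500, 600)))
        events = classify_splice_event(novel, [ref_minus])
        # on the minus strand the genomic left end is the termination
        assert [e.event_type for e in events] == ["alt_termination"]

    def test_alternative_internal_exon(self):
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((100, 200), (230, 260), (300, 400),
                                 (500, 600)))
        events = classify_splice_event(novel, [self.REF])
        assert [e.event_type for e in events] == ["alternative_exon"]
        assert events[0].coordinates == ((230, 260),)

    def test_no_reference_unclassified(self):
        novel = TranscriptModel("n", "g", "chr2", "+", ((0, 50),))
        events = classify_splice_event(novel, [self.REF])
        assert [e.event_type for e in events] == ["unclassified"]

    def test_best_reference_by_shared_junctions(self):
        other = TranscriptModel("far", "g", "chr1", "+",
                                ((1000, 1100), (1200, 1300)))
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((100, 200), (500, 600)))
        events = classify_splice_event(novel, [other, self.REF])
        assert events[0].reference_id == "ref"

    def test_co_occurring_events(self):
        four = TranscriptModel("r4", "g", "chr1", "+",
                               ((100, 200), (300, 400), (500, 600),
                                (700, 800)))
        novel = TranscriptModel("n", "g", "chr1", "+",
                                ((100, 200), (500, 600), (700, 750)))
        kinds = {e.event_type for e in classify_splice_event(novel, [four])}
        assert kinds == {"exon_skip", "alt_termination"}
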