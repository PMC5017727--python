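"""GC-matched shuffling, empirical p-values, Bonferroni, hypergeometric test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forksense import (
    AnalysisConfig,
    FeatureSet,
    GenomeSequence,
    GenomicInterval,
    bonferroni_threshold,
    empirical_pvalue,
    enrichment_analysis,
    gc_content,
    hypergeometric_rate_test,
    shuffle_gc_matched,
)
from forksense.enrichment import GCWindowIndex, ShuffleError


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 0.0), ("GGCC", 1.0), ("ACGT", 0.5), ("ACGTN", 0.5)]
    )
    def test_values(self, seq, expected):
        g = GenomeSequence({"c": seq})
        assert gc_content(g, GenomicInterval("c", 0, len(seq))) == expected

    def test_all_n_rejected(self):
        g = GenomeSequence({"c": "NNNN"})
        with pytest.raises(ValueError, match="N"):
            gc_content(g, GenomicInterval("c", 0, 4))

    def test_index_agrees_with_direct_count(self, toy_genome, rng):
        index = GCWindowIndex(toy_genome)
        for _ in range(50):
            chrom = rng.choice(toy_genome.chroms)
            start = int(rng.integers(0, toy_genome.lengths[chrom] - 100))
            end = start + int(rng.integers(1, 100))
            iv = GenomicInterval(chrom, start, end)
            assert index.gc_fraction(chrom, start, end) == pytest.approx(
                gc_content(toy_genome, iv)
            )


class TestShuffle:
    def test_uniform_genome_preserves_length_and_chrom(self, rng):
        g = GenomeSequence({"chrI": "ACGT" * 5000, "chrII": "ACGT" * 2500})
        peaks = [
            GenomicInterval("chrI", 100, 400, 30.0),
            GenomicInterval("chrII", 0, 50),
            GenomicInterval("chrI", 19000, 19990),
        ]
        shuffled = shuffle_gc_matched(peaks, g, tolerance=0.02, rng=rng)
        for orig, new in zip(peaks, shuffled):
            assert new.chrom == orig.chrom
            assert new.length == orig.length
            assert new.strength == orig.strength

    def test_unique_matching_window_found(self, rng):
        # one GC-rich island; exact matching (tolerance 0) must land on it
        seq = "AT" * 500 + "GC" * 10 + "AT" * 500
        g = GenomeSequence({"c": seq})
        peak = GenomicInterval("c", 1000, 1020)  # the all-GC window
        # verify by exhaustive enumeration that only one window has GC 1.0
        index = GCWindowIndex(g)
        starts = np.arange(len(seq) - 20 + 1)
        gcs = index.gc_fraction("c", starts, starts + 20)
        assert (gcs == 1.0).sum() == 1
        shuffled = shuffle_gc_matched([peak], g, tolerance=0.0, rng=rng)
        assert (shuffled[0].start, shuffled[0].end) == (1000, 1020)

    def test_gc_within_tolerance_over_many_shuffles(self, rng):
        spec_tol = 0.05
        g = GenomeSequence(
            {"c": "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=50000))}
        )
        index = GCWindowIndex(g)
        peaks = [
            GenomicInterval("c", int(s), int(s) + 200)
            for s in rng.integers(0, 49800, size=50)
        ]
        targets = [index.gc_fraction(p.chrom, p.start, p.end) for p in peaks]
        for _ in range(20):
            shuffled = shuffle_gc_matched(peaks, g, index, tolerance=spec_tol, rng=rng)
            for t, s in zip(targets, shuffled):
                assert abs(index.gc_fraction(s.chrom, s.start, s.end) - t) <= spec_tol

    def test_unplaceable_peaks_raise_named_errors(self, toy_genome, rng):
        with pytest.raises(ShuffleError, match="chrX"):
            shuffle_gc_matched(
                [GenomicInterval("chrX", 0, 100)], toy_genome, rng=rng
            )
        g = GenomeSequence({"c": "N" * 500 + "ACGT" * 500})
        with pytest.raises(ShuffleError, match="c:0-100"):
            shuffle_gc_matched([GenomicInterval("c", 0, 100)], g, rng=rng)
        with pytest.raises(ShuffleError, match="longer than"):
            shuffle_gc_matched(
                [GenomicInterval("c", 0, 100)],
                GenomeSequence({"c": "ACGT" * 10}),
                rng=rng,
            )


class TestEmpiricalPValue:
    def test_below_resolution_reported_as_bound(self):
        pv = empirical_pvalue(50, [1] * 1000)
        assert pv.below_resolution
        assert pv.p == 0.0
        assert pv.reported == 0.001
        assert str(pv) == "<0.001"

    def test_observed_zero_gives_one(self):
        pv = empirical_pvalue(0, [0, 1, 2, 3])
        assert pv.p == 1.0 and not pv.below_resolution

    def test_definition_example(self):
        pv = empirical_pvalue(6, [3, 5, 7, 9])
        assert pv.p == 0.5

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
        st.integers(0, 25),
        st.integers(0, 25),
    )
    def test_antitone_and_integer_valued(self, permuted, obs1, obs2):
        lo, hi = sorted((obs1, obs2))
        p_lo, p_hi = empirical_pvalue(lo, permuted), empirical_pvalue(hi, permuted)
        assert p_lo.p >= p_hi.p
        for pv in (p_lo, p_hi):
            n_at_least = pv.p * pv.n_permutations
            assert n_at_least == pytest.approx(round(n_at_least))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 16, 0.003125), (0.05, 1, 0.05), (0.05, 10, 0.005)]
    )
    def test_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestHypergeometric:
    def test_subset_equals_total(self):
        assert hypergeometric_rate_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_closed_form(self):
        # P(X >= 2) with 2 draws from 4 items of which 2 are hits = 1/6
        assert hypergeometric_rate_test(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_zero_hits_in_subset(self):
        assert hypergeometric_rate_test(0, 5, 3, 20) == pytest.approx(1.0)

    def test_incoherent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_rate_test(6, 5, 10, 20)


class TestEnrichmentAnalysis:
    def test_uniform_null_matches_analytic_expectation(self, rng):
        # tolerance 1 disables GC matching: placement is uniform, so the mean
        # permuted association count of a single-position feature equals
        # n_features * P(a random peak lands within the window) analytically.
        chrom_len = 20_000
        g = GenomeSequence({"c": "ACGT" * (chrom_len // 4)})
        window = 100
        peak_len = 50
        features = FeatureSet(
            "pts",
            [GenomicInterval("c", s, s + 1) for s in range(2000, 18000, 1000)],
        )
        peaks = [GenomicInterval("c", 0, peak_len)]
        config = AnalysisConfig(
            n_permutations=1000, gc_tolerance=1.0, seed=5, peak_window_bp=window
        )
        results = enrichment_analysis(peaks, [features], g, config, rng=rng)
        counts = results[0].permutation_counts
        # a feature at position x is hit iff peak start is in
        # [x - window - peak_len, x + window], intersected with the valid range
        n_starts = chrom_len - peak_len + 1
        p_hit_one = (2 * window + peak_len + 1) / n_starts
        expect = features.n * p_hit_one
        se = math.sqrt(features.n * p_hit_one * (1 - p_hit_one) / len(counts))
        assert abs(counts.mean() - expect) <= 3 * se

    def test_single_permutation_boundary(self, toy_genome):
        features = FeatureSet("f", [GenomicInterval("chrI", 0, 100)])
        peaks = [GenomicInterval("chrI", 5000, 5200)]
        config = AnalysisConfig(n_permutations=1, seed=3, gc_tolerance=1.0)
        (res,) = enrichment_analysis(peaks, [features], toy_genome, config)
        assert res.pvalue.p in (0.0, 1.0)

    def test_shared_shuffles_reproducible_from_seed(self, study, fast_config):
        peaks = study.peaks["pfh1_wt"].intervals
        a = enrichment_analysis(peaks, study.features, study.genome, fast_config)
        b = enrichment_analysis(peaks, study.features, study.genome, fast_config)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.permutation_counts, rb.permutation_counts)
            assert ra.pvalue == rb.pvalue
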