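"""Cross-condition peak comparison against enumeration oracles."""

import itertools

import numpy as np
import pytest

from forksense import (
    FeatureSet,
    GenomicInterval,
    PeakTable,
    distance,
    fraction_stronger,
    match_conditions,
    merge_union,
    stratify_by_feature,
    venn_counts,
    wilcoxon_paired,
)
from forksense.dynamics import RegionMatch


def _table(condition, triples):
    return PeakTable(
        condition,
        [GenomicInterval(c, s, e, strength) for c, s, e, strength in triples],
    )


def _matches(pairs):
    return [
        RegionMatch(GenomicInterval("c", 100 * i, 100 * i + 10), float(a), float(b))
        for i, (a, b) in enumerate(pairs)
    ]


def signed_rank_two_sided_p(diffs):
    """Exact two-sided signed-rank p by dynamic programming over rank sums.

    Assumes no ties among |diffs| and no zeros; enumerates the null
    distribution of W+ (the polynomial product of (1 + x^rank)).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_plus = int(ranks[diffs > 0].sum())
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    counts /= 2.0**n
    cdf = counts[: w_plus + 1].sum()
    sf = counts[w_plus:].sum()
    return min(1.0, 2 * min(cdf, sf))


class TestMatchConditions:
    def test_zero_imputation(self):
        a = _table("a", [("chrI", 0, 10, 30.0)])
        b = _table("b", [])
        (m,) = match_conditions(a, b)
        assert (m.strength_a, m.strength_b) == (30.0, 0.0)

    def test_overlapping_peaks_merge_to_one_region(self):
        a = _table("a", [("chrI", 0, 10, 30.0)])
        b = _table("b", [("chrI", 5, 15, 50.0)])
        (m,) = match_conditions(a, b)
        assert (m.region.start, m.region.end) == (0, 15)
        assert (m.strength_a, m.strength_b) == (30.0, 50.0)

    def test_identity_lands_on_diagonal(self):
        a = _table("a", [("chrI", 0, 10, 30.0), ("chrII", 50, 80, 12.0)])
        for m in match_conditions(a, a):
            assert m.strength_a == m.strength_b > 0

    def test_symmetric_up_to_column_swap(self, study):
        ab = match_conditions(study.peaks["cdc20_wt"], study.peaks["cdc20_depleted"])
        ba = match_conditions(study.peaks["cdc20_depleted"], study.peaks["cdc20_wt"])
        assert [(m.strength_a, m.strength_b) for m in ab] == [
            (m.strength_b, m.strength_a) for m in ba
        ]

    def test_max_over_fragmented_peaks(self):
        a = _table("a", [("chrI", 0, 10, 30.0), ("chrI", 8, 20, 45.0)])
        b = _table("b", [("chrI", 5, 12, 50.0)])
        (m,) = match_conditions(a, b)
        assert m.strength_a == 45.0

    def test_missing_strengths_refused(self):
        a = PeakTable("a", [GenomicInterval("chrI", 0, 10)])
        with pytest.raises(ValueError, match="without strengths"):
            match_conditions(a, a)


class TestFractionStronger:
    def test_enumeration(self):
        assert fraction_stronger(_matches([(1, 2), (2, 3), (3, 1)])) == pytest.approx(2 / 3)

    def test_ties_count_in_denominator_only(self):
        assert fraction_stronger(_matches([(5, 5), (5, 5)])) == 0.0

    def test_b_only_region_counts_as_stronger(self):
        assert fraction_stronger(_matches([(0, 5)])) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_stronger([])

    def test_complement_bound(self, study):
        ab = match_conditions(study.peaks["gh2a_wt"], study.peaks["gh2a_depleted"])
        ba = match_conditions(study.peaks["gh2a_depleted"], study.peaks["gh2a_wt"])
        f_ab, f_ba = fraction_stronger(ab), fraction_stronger(ba)
        ties = sum(1 for m in ab if m.strength_a == m.strength_b)
        assert f_ab + f_ba <= 1.0 + 1e-12
        if ties == 0:
            assert f_ab + f_ba == pytest.approx(1.0)


class TestWilcoxon:
    def test_antisymmetric_differences_give_p_one(self):
        pairs = [(10, 10 + d) for d in (1, 2, 3)] + [(10 + d, 10) for d in (1, 2, 3)]
        res = wilcoxon_paired(_matches(pairs))
        assert res.p == pytest.approx(1.0)

    def test_all_stronger_matches_exact_tail(self):
        # 20 pairs all strictly stronger in B: W- = 0, two-sided p = 2 / 2^20
        pairs = [(10.0, 10.0 + i) for i in range(1, 21)]
        res = wilcoxon_paired(_matches(pairs))
        assert res.p == pytest.approx(2 / 2**20)
        assert res.n_used == 20 and not res.approx_zero

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_dp_enumeration_oracle(self, n, rng):
        for _ in range(10):
            # distinct magnitudes, no zeros, random signs
            mags = np.sort(rng.uniform(1, 100, size=n))
            diffs = mags * rng.choice([-1, 1], size=n)
            pairs = [(50.0, 50.0 + d) for d in diffs]
            res = wilcoxon_paired(_matches(pairs))
            assert res.p == pytest.approx(signed_rank_two_sided_p(diffs))

    def test_zero_differences_dropped(self):
        pairs = [(5, 5)] * 3 + [(1.0, 2.0), (2.0, 4.0)]
        res = wilcoxon_paired(_matches(pairs))
        assert res.n_used == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired(_matches([(5, 5), (7, 7)]))

    def test_large_shift_is_overwhelming(self, rng):
        base = rng.uniform(20, 80, size=1000)
        pairs = list(zip(base, base + 10 + rng.normal(0, 1, size=1000)))
        res = wilcoxon_paired(_matches(pairs))
        assert res.p < 1e-10


class TestStratify:
    def test_no_features_empty(self):
        matches = _matches([(1, 2)])
        assert stratify_by_feature(matches, FeatureSet("f", []), 100) == []

    def test_all_inside_identity(self):
        matches = _matches([(1, 2), (3, 4)])
        features = FeatureSet("f", [m.region for m in matches])
        assert stratify_by_feature(matches, features, 0) == matches

    def test_matches_brute_force(self, rng):
        matches = [
            RegionMatch(GenomicInterval("c", int(s), int(s) + 20), 1.0, 2.0)
            for s in rng.integers(0, 5000, size=30)
        ]
        features = FeatureSet(
            "f",
            [GenomicInterval("c", int(s), int(s) + 50) for s in rng.integers(0, 5000, size=10)],
        )
        for window in (0, 25, 200):
            expected = [
                m
                for m in matches
                if any(distance(m.region, f) <= window for f in features.intervals)
            ]
            assert stratify_by_feature(matches, features, window) == expected


class TestVenn:
    def test_identical_sets_all_shared(self):
        a = _table("a", [("chrI", 0, 10, 1.0), ("chrI", 50, 60, 2.0)])
        vc = venn_counts(a, a)
        assert vc == (0, 0, 2, 2)

    def test_disjoint_sets(self):
        a = _table("a", [("chrI", 0, 10, 1.0)])
        b = _table("b", [("chrII", 0, 10, 1.0)])
        assert venn_counts(a, b) == (1, 1, 0, 0)

    def test_partition_identity(self, study):
        for mark in ("cdc20", "gh2a"):
            wt = study.peaks[f"{mark}_wt"]
            dep = study.peaks[f"{mark}_depleted"]
            vc = venn_counts(wt, dep)
            assert vc.only_a + vc.shared_a == wt.n
            assert vc.only_b + vc.shared_b == dep.n


class TestShiftMonotonicity:
    def test_fraction_stronger_increases_with_planted_shift(self):
        from dataclasses import replace

        from forksense import SimulationSpec, simulate_study

        fractions = []
        for shift in (0.0, 5.0, 10.0, 20.0):
            spec = SimulationSpec(
                n_chromosomes=2,
                chromosome_length_bp=100_000,
                n_peaks={
                    "pfh1_wt": 10,
                    "cdc20_wt": 60,
                    "cdc20_depleted": 60,
                    "gh2a_wt": 10,
                    "gh2a_depleted": 10,
                },
                shared_fraction=1.0,
                depleted_shift=shift,
                seed=21,
            )
            st = simulate_study(spec)
            m = match_conditions(st.peaks["cdc20_wt"], st.peaks["cdc20_depleted"])
            fractions.append(fraction_stronger(m))
        assert fractions == sorted(fractions)
        assert fractions[-1] > fractions[0]
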