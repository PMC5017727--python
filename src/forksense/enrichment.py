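"""GC-matched permutation test for peak-feature association.

The null model scrambles peak locations while preserving, for every peak,
its length, its chromosome, and (within a tolerance) its GC content, and
asks how often random placements associate with an annotation class at
least as strongly as the real peaks do.  The empirical p-value is the
fraction of the N permutations reaching the observed association count;
when no permutation does, the p-value is reported as the resolution bound
"< 1/N" rather than 0.  Family-wise error across annotation classes is
controlled with a Bonferroni threshold.

GC matching uses an exact per-chromosome prefix-sum index, so the GC of
any candidate window is an O(1) lookup; N bases are excluded from both the
numerator and the denominator, and all-N windows are never sampled.  When
no qualifying position exists at the requested tolerance, the tolerance is
doubled (up to 5 times, 1000 draws each) before giving up with an error
naming the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .intervals import FeatureSet, GenomicInterval, PeakIndex, associate_features
from .io import GenomeSequence

__all__ = [
    "ShuffleError",
    "GCWindowIndex",
    "gc_content",
    "shuffle_gc_matched",
    "EmpiricalPValue",
    "empirical_pvalue",
    "bonferroni_threshold",
    "AssociationResult",
    "enrichment_analysis",
    "hypergeometric_rate_test",
]


class ShuffleError(RuntimeError):
    """No qualifying placement found for a peak within the relaxation schedule."""


class GCWindowIndex:
    """Prefix sums of G/C and non-N base counts per chromosome.

    ``gc_fraction`` returns (#G + #C) / (#A + #C + #G + #T) for any window
    in O(1); windows containing only N bases yield NaN.
    """

    def __init__(self, genome: GenomeSequence):
        self.lengths = genome.lengths
        self._cum_gc: dict[str, np.ndarray] = {}
        self._cum_ok: dict[str, np.ndarray] = {}
        for chrom, seq in genome.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            is_ok = is_gc | (arr == ord("A")) | (arr == ord("T"))
            self._cum_gc[chrom] = np.concatenate(
                ([0], np.cumsum(is_gc, dtype=np.int64))
            )
            self._cum_ok[chrom] = np.concatenate(
                ([0], np.cumsum(is_ok, dtype=np.int64))
            )

    def gc_fraction(
        self, chrom: str, starts: np.ndarray | int, ends: np.ndarray | int
    ) -> np.ndarray | float:
        cum_gc, cum_ok = self._cum_gc[chrom], self._cum_ok[chrom]
        gc = cum_gc[ends] - cum_gc[starts]
        ok = cum_ok[ends] - cum_ok[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(ok > 0, gc / np.maximum(ok, 1), np.nan)
        if np.isscalar(starts) or np.ndim(starts) == 0:
            return float(frac)
        return frac


def gc_content(genome: GenomeSequence, interval: GenomicInterval) -> float:
    """GC fraction of an interval, with N bases excluded from both counts."""
    seq = genome.fetch(interval.chrom, interval.start, interval.end)
    gc = seq.count("G") + seq.count("C")
    ok = gc + seq.count("A") + seq.count("T")
    if ok == 0:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "contains only N bases; GC undefined"
        )
    return gc / ok


def shuffle_gc_matched(
    peaks: Sequence[GenomicInterval],
    genome: GenomeSequence,
    index: GCWindowIndex | None = None,
    tolerance: float = 0.02,
    rng: np.random.Generator | None = None,
    *,
    batch: int = 1000,
    max_relaxations: int = 5,
) -> list[GenomicInterval]:
    """Random relocation of each peak preserving length, chromosome and GC.

    Each output interval has exactly the length and chromosome of the
    corresponding input, a GC content within ``tolerance`` of the original
    (doubling the tolerance after each ``batch`` failed draws, at most
    ``max_relaxations`` times), and a start position uniform over the
    qualifying windows.  Strength and label are carried over.
    """
    if index is None:
        index = GCWindowIndex(genome)
    if rng is None:
        rng = np.random.default_rng()
    out: list[GenomicInterval] = []
    for peak in peaks:
        if peak.chrom not in index.lengths:
            raise ShuffleError(
                f"peak {peak.chrom}:{peak.start}-{peak.end}: chromosome not in genome"
            )
        length = peak.length
        max_start = index.lengths[peak.chrom] - length
        if max_start < 0:
            raise ShuffleError(
                f"peak {peak.chrom}:{peak.start}-{peak.end} longer than its chromosome"
            )
        target = index.gc_fraction(peak.chrom, peak.start, peak.end)
        if np.isnan(target):
            raise ShuffleError(
                f"peak {peak.chrom}:{peak.start}-{peak.end} is all-N; GC undefined"
            )
        tol = tolerance
        placed = False
        for _ in range(max_relaxations + 1):
            cand = rng.integers(0, max_start + 1, size=batch)
            gc = index.gc_fraction(peak.chrom, cand, cand + length)
            ok = np.abs(gc - target) <= tol  # NaN (all-N) compares False
            hits = np.flatnonzero(ok)
            if hits.size:
                start = int(cand[hits[0]])
                out.append(
                    GenomicInterval(
                        peak.chrom, start, start + length, peak.strength, peak.label
                    )
                )
                placed = True
                break
            tol = tol * 2 if tol > 0 else 0.01
        if not placed:
            raise ShuffleError(
                f"no GC-matched placement for peak {peak.chrom}:{peak.start}-"
                f"{peak.end} (target GC {target:.3f}) after {max_relaxations} "
                "tolerance relaxations"
            )
    return out


@dataclass(frozen=True)
class EmpiricalPValue:
    """Permutation p-value with explicit resolution bound.

    ``count`` is the number of permutations reaching the observed statistic;
    ``p = count / n_permutations``.  When count is 0 the true p-value is
    below the resolution of the permutation scheme and is reported as the
    bound "< 1/N", never as 0.
    """

    count: int
    n_permutations: int

    @property
    def p(self) -> float:
        return self.count / self.n_permutations

    @property
    def below_resolution(self) -> bool:
        return self.count == 0

    @property
    def reported(self) -> float:
        """Numeric value to report: the bound 1/N when below resolution."""
        return max(self.count, 1) / self.n_permutations

    def __str__(self) -> str:
        if self.below_resolution:
            return f"<{1 / self.n_permutations:g}"
        return f"{self.p:g}"


def empirical_pvalue(observed: int, permuted: Sequence[int]) -> EmpiricalPValue:
    """Fraction of permuted counts >= observed, with a below-resolution flag."""
    permuted = np.asarray(permuted)
    if permuted.size == 0:
        raise ValueError("permuted counts must be nonempty")
    count = int((permuted >= observed).sum())
    return EmpiricalPValue(count=count, n_permutations=int(permuted.size))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


@dataclass
class AssociationResult:
    """Observed association of one annotation class with one peak set."""

    feature_name: str
    n_features: int
    n_associated: int
    permutation_counts: np.ndarray
    pvalue: EmpiricalPValue
    significant: bool

    @property
    def fraction(self) -> float:
        return self.n_associated / self.n_features


def enrichment_analysis(
    peaks: Sequence[GenomicInterval],
    feature_sets: Sequence[FeatureSet],
    genome: GenomeSequence,
    config: AnalysisConfig,
    *,
    window_bp: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[AssociationResult]:
    """Permutation enrichment of a peak set against several annotation classes.

    One shared set of ``config.n_permutations`` GC/length/chromosome-matched
    shuffles scores every feature class, so a single seed reproduces the
    whole table.  The significance flag applies a Bonferroni threshold of
    ``alpha / len(feature_sets)`` to each empirical p-value (below-resolution
    p-values count as significant whenever the bound 1/N is below the
    threshold).
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    if window_bp is None:
        window_bp = config.peak_window_bp
    if rng is None:
        rng = np.random.default_rng(config.seed)
    index = GCWindowIndex(genome)
    observed = np.array(
        [associate_features(fs, peaks, window_bp)[1] for fs in feature_sets]
    )
    n_perm = config.n_permutations
    perm_counts = np.zeros((n_perm, len(feature_sets)), dtype=np.int64)
    for j in range(n_perm):
        shuffled = shuffle_gc_matched(
            peaks, genome, index, config.gc_tolerance, rng
        )
        peak_index = PeakIndex(shuffled)
        for k, fs in enumerate(feature_sets):
            perm_counts[j, k] = int(
                (peak_index.min_gaps(fs.intervals) <= window_bp).sum()
            )
    threshold = bonferroni_threshold(config.alpha, len(feature_sets))
    results = []
    for k, fs in enumerate(feature_sets):
        pv = empirical_pvalue(int(observed[k]), perm_counts[:, k])
        results.append(
            AssociationResult(
                feature_name=fs.name,
                n_features=fs.n,
                n_associated=int(observed[k]),
                permutation_counts=perm_counts[:, k].copy(),
                pvalue=pv,
                significant=pv.reported < threshold,
            )
        )
    return results


def hypergeometric_rate_test(
    k_hit_in_subset: int, n_subset: int, k_hit_total: int, n_total: int
) -> float:
    """Upper-tail hypergeometric probability of >= k hits in the subset.

    Tests whether a subset of a population (e.g. the most highly transcribed
    genes among all RNA polymerase II genes) is hit by peaks more often than
    expected from the population-wide hit rate.
    """
    if not (
        0 <= k_hit_in_subset <= n_subset <= n_total
        and k_hit_in_subset <= k_hit_total <= n_total
        and k_hit_total - k_hit_in_subset <= n_total - n_subset
    ):
        raise ValueError(
            "incoherent counts: need subset within population and hits within both"
        )
    return float(stats.hypergeom.sf(k_hit_in_subset - 1, n_total, k_hit_total, n_subset))
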