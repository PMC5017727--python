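"""Cross-condition peak comparison.

Peaks from two conditions (e.g. Cdc20 occupancy in wild-type vs
helicase-depleted cells) are matched on merged genomic regions: every
region carrying a peak in at least one condition becomes one paired
observation, with the per-condition strength set to 0 when that condition
has no peak there.  On the matched pairs we report the fraction of regions
strictly stronger in condition B, a two-sided Wilcoxon signed-rank test on
the paired strengths (zero differences dropped; p-values below 1e-50
flagged as "~0"), per-annotation-class stratification, and Venn-style
overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .intervals import FeatureSet, GenomicInterval, PeakIndex, merge_union, overlap_counts
from .io import PeakTable

__all__ = [
    "RegionMatch",
    "WilcoxonResult",
    "ComparisonResult",
    "VennCounts",
    "match_conditions",
    "fraction_stronger",
    "wilcoxon_paired",
    "stratify_by_feature",
    "venn_counts",
    "compare_conditions",
    "plot_strength_scatter",
]

APPROX_ZERO_P = 1e-50  # below this, report "~0"
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class RegionMatch:
    """One merged region with its per-condition peak strengths (0 = absent)."""

    region: GenomicInterval
    strength_a: float
    strength_b: float


class VennCounts(NamedTuple):
    only_a: int
    only_b: int
    shared_a: int  # A peaks within the window of some B peak
    shared_b: int  # B peaks within the window of some A peak


@dataclass(frozen=True)
class WilcoxonResult:
    p: float
    statistic: float
    n_used: int  # nonzero differences entering the test
    approx_zero: bool

    def __str__(self) -> str:
        return "~0" if self.approx_zero else f"{self.p:g}"


@dataclass
class ComparisonResult:
    stratum: str
    n_regions: int
    fraction_stronger_b: float
    wilcoxon: WilcoxonResult | None


def match_conditions(peaks_a: PeakTable, peaks_b: PeakTable) -> list[RegionMatch]:
    """Pair the two conditions on merged regions, imputing 0 for absent peaks.

    Regions are the merged union of both peak sets; the strength assigned to
    a region for a condition is the maximum strength among that condition's
    peaks overlapping the region (a merged region usually holds one peak per
    condition; the maximum is insensitive to peak fragmentation).  Both
    tables must carry strengths.
    """
    for table in (peaks_a, peaks_b):
        if not table.has_strengths:
            raise ValueError(
                f"peak table {table.condition!r} has peaks without strengths; "
                "strength-dependent comparison refuses to impute them"
            )
    regions = merge_union(peaks_a.intervals, peaks_b.intervals)
    if not regions:
        return []
    # every peak lies entirely inside exactly one merged region
    starts_by_chrom: dict[str, np.ndarray] = {}
    region_ids_by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        region_ids_by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, ids in region_ids_by_chrom.items():
        starts_by_chrom[chrom] = np.array([regions[i].start for i in ids])

    def accumulate(table: PeakTable, out: np.ndarray) -> None:
        for peak in table.intervals:
            ids = region_ids_by_chrom[peak.chrom]
            pos = int(np.searchsorted(starts_by_chrom[peak.chrom], peak.start, "right")) - 1
            rid = ids[pos]
            out[rid] = max(out[rid], peak.strength)

    strength_a = np.zeros(len(regions))
    strength_b = np.zeros(len(regions))
    accumulate(peaks_a, strength_a)
    accumulate(peaks_b, strength_b)
    return [
        RegionMatch(region=r, strength_a=float(a), strength_b=float(b))
        for r, a, b in zip(regions, strength_a, strength_b)
    ]


def fraction_stronger(matches: Sequence[RegionMatch]) -> float:
    """Fraction of matched regions strictly stronger in condition B.

    Ties are excluded from the numerator but kept in the denominator, and a
    region where only condition B has a peak counts as stronger in B.
    """
    if not matches:
        raise ValueError("fraction_stronger undefined on an empty match list")
    stronger = sum(1 for m in matches if m.strength_b > m.strength_a)
    return stronger / len(matches)


def wilcoxon_paired(matches: Sequence[RegionMatch]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired region strengths.

    Zero differences are dropped (Wilcoxon's convention).  The exact null
    distribution is used for up to 25 nonzero differences; beyond that the
    normal approximation with continuity correction is used.  p-values below
    1e-50 are flagged ``approx_zero`` and printed as "~0".
    """
    diffs = np.array([m.strength_b - m.strength_a for m in matches])
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    n = int(diffs.size)
    exact = n <= EXACT_WILCOXON_MAX_N
    res = stats.wilcoxon(
        diffs,
        zero_method="wilcox",
        alternative="two-sided",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    p = float(res.pvalue)
    return WilcoxonResult(
        p=p, statistic=float(res.statistic), n_used=n, approx_zero=p < APPROX_ZERO_P
    )


def stratify_by_feature(
    matches: Sequence[RegionMatch], features: FeatureSet, window_bp: int
) -> list[RegionMatch]:
    """Matches whose region lies within ``window_bp`` of a feature of the class."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not matches or features.n == 0:
        return []
    index = PeakIndex(features.intervals)
    gaps = index.min_gaps([m.region for m in matches])
    return [m for m, g in zip(matches, gaps) if g <= window_bp]


def venn_counts(
    peaks_a: PeakTable | Sequence[GenomicInterval],
    peaks_b: PeakTable | Sequence[GenomicInterval],
    window_bp: int = 0,
) -> VennCounts:
    """Venn-style overlap of two peak sets.

    ``shared_a`` counts A peaks within ``window_bp`` of some B peak and vice
    versa (the two shared counts can differ when peaks merge or split across
    conditions, which is why both are reported).
    """
    a = list(peaks_a.intervals if isinstance(peaks_a, PeakTable) else peaks_a)
    b = list(peaks_b.intervals if isinstance(peaks_b, PeakTable) else peaks_b)
    shared_a, shared_b = overlap_counts(a, b, window_bp)
    return VennCounts(
        only_a=len(a) - shared_a,
        only_b=len(b) - shared_b,
        shared_a=shared_a,
        shared_b=shared_b,
    )


def compare_conditions(
    peaks_a: PeakTable,
    peaks_b: PeakTable,
    strata: Sequence[FeatureSet] = (),
    window_bp: int = 300,
) -> list[ComparisonResult]:
    """Overall and per-stratum strength comparison between two conditions."""
    matches = match_conditions(peaks_a, peaks_b)
    out = []
    subsets: list[tuple[str, list[RegionMatch]]] = [("all", list(matches))]
    for fs in strata:
        subsets.append((fs.name, stratify_by_feature(matches, fs, window_bp)))
    for name, subset in subsets:
        if not subset:
            out.append(ComparisonResult(name, 0, float("nan"), None))
            continue
        try:
            wtest = wilcoxon_paired(subset)
        except ValueError:
            wtest = None
        out.append(
            ComparisonResult(
                stratum=name,
                n_regions=len(subset),
                fraction_stronger_b=fraction_stronger(subset),
                wilcoxon=wtest,
            )
        )
    return out


def plot_strength_scatter(
    matches: Sequence[RegionMatch],
    path: str,
    label_a: str = "condition A",
    label_b: str = "condition B",
) -> None:
    """Scatter of per-region strengths, absent peaks plotted at 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = [m.strength_a for m in matches]
    b = [m.strength_b for m in matches]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(a, b, s=8, alpha=0.5, edgecolors="none")
    lim = max(max(a, default=1), max(b, default=1)) * 1.05
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel(f"{label_a} peak strength (-10*log10 p)")
    ax.set_ylabel(f"{label_b} peak strength (-10*log10 p)")
    if matches:
        pct = 100 * fraction_stronger(matches)
        ax.text(0.95, 0.05, f"{pct:.0f}%", transform=ax.transAxes, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
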