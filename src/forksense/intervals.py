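"""Genomic interval primitives and windowed peak-feature association.

All coordinates follow the BED convention: ``start`` is 0-based inclusive,
``end`` is exclusive.  Distances between intervals are edge-to-edge gaps in
base pairs; overlapping (or touching) intervals are at distance 0 and
intervals on different chromosomes are infinitely far apart.

The "within *w* bp" association used throughout the package means
``distance(feature, peak) <= w``, which matches the window semantics of
``bedtools window -w``.  A feature associated with several peaks counts
once: the association statistic is the number of associated features, not
the number of feature-peak pairs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "FeatureSet",
    "distance",
    "associate_features",
    "overlap_counts",
    "merge_union",
    "PeakIndex",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an optional peak strength.

    ``strength`` is on the MACS scale, -10*log10 of the peak-calling
    p-value, so larger is more significant; 0 is allowed.
    """

    chrom: str
    start: int
    end: int
    strength: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strength is not None and not self.strength >= 0:
            raise ValueError(
                f"strength must be >= 0, got {self.strength} for "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return self.length


@dataclass
class FeatureSet:
    """A named annotation class (tRNA genes, NDRs, origins, ...)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return self.n


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge gap in bp; 0 if overlapping/touching, inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return float(max(a.start - b.end, b.start - a.end, 0))


class PeakIndex:
    """Per-chromosome sorted arrays supporting vectorised nearest-gap queries.

    For each chromosome the interval starts are sorted and a running maximum
    of the ends is kept, so the minimum gap from a query interval to any
    indexed interval is computed with one ``searchsorted`` per query batch.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        n = 0
        for iv in intervals:
            by_chrom[iv.chrom].append(iv)
            n += 1
        self.n = n
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            ends_cummax = np.maximum.accumulate(ends[order])
            self._arrays[chrom] = (starts, ends_cummax)

    def min_gaps(self, queries: Sequence[GenomicInterval]) -> np.ndarray:
        """Minimum gap from each query to the indexed set (inf if none on chrom)."""
        out = np.full(len(queries), np.inf)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, q in enumerate(queries):
            by_chrom[q.chrom].append(i)
        for chrom, idxs in by_chrom.items():
            if chrom not in self._arrays:
                continue
            starts, ends_cummax = self._arrays[chrom]
            q_start = np.array([queries[i].start for i in idxs], dtype=np.int64)
            q_end = np.array([queries[i].end for i in idxs], dtype=np.int64)
            pos = np.searchsorted(starts, q_end, side="left")
            right = np.where(pos < len(starts), starts[np.minimum(pos, len(starts) - 1)] - q_end, np.inf)
            left = np.where(pos > 0, q_start - ends_cummax[np.maximum(pos - 1, 0)], np.inf)
            out[idxs] = np.maximum(np.minimum(right, left), 0.0)
        return out


def associate_features(
    features: FeatureSet,
    peaks: Sequence[GenomicInterval],
    window_bp: int,
    *,
    count_pairs: bool = False,
) -> tuple[np.ndarray, int]:
    """Which features have a peak within ``window_bp``, and how many.

    Returns ``(mask, count)`` where ``mask[i]`` is True iff some peak lies
    within ``window_bp`` of feature *i*.  By default ``count`` is the number
    of associated features (each feature counted once regardless of how many
    peaks it touches); with ``count_pairs=True`` it is the number of
    feature-peak pairs within the window instead, and the mask is unchanged.

    Raises ``ValueError`` on an empty feature set, for which the association
    fraction would be undefined.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if features.n == 0:
        raise ValueError(
            f"feature set {features.name!r} is empty; association fraction undefined"
        )
    if not peaks:
        return np.zeros(features.n, dtype=bool), 0
    index = PeakIndex(peaks)
    mask = index.min_gaps(features.intervals) <= window_bp
    if not count_pairs:
        return mask, int(mask.sum())
    pairs = 0
    for f in features.intervals:
        for p in peaks:
            if distance(f, p) <= window_bp:
                pairs += 1
    return mask, pairs


def overlap_counts(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    window_bp: int = 0,
) -> tuple[int, int]:
    """(#A intervals within window of some B, #B intervals within window of some A)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    n_a = n_b = 0
    if set_a and set_b:
        n_a = int((PeakIndex(set_b).min_gaps(set_a) <= window_bp).sum())
        n_b = int((PeakIndex(set_a).min_gaps(set_b) <= window_bp).sum())
    return n_a, n_b


def merge_union(*interval_lists: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal set of maximal disjoint intervals covering the union of the inputs.

    Touching intervals ([0,10) and [10,20)) are merged since they cover a
    contiguous run of bases.  Output is sorted by chromosome name then start;
    strengths and labels are dropped.
    """
    flat = [iv for lst in interval_lists for iv in lst]
    if not flat:
        return []
    flat.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = flat[0].chrom, flat[0].start, flat[0].end
    for iv in flat[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged
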