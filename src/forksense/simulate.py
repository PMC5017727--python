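"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a fission-yeast-style ChIP-seq / IP-MS study at
desk scale: a small multi-chromosome genome with spatially varying GC
content, annotation classes (tRNA-like genes, 5S-rRNA-like genes, highly
expressed genes, nucleosome-depleted regions, origins, ...), peak sets
planted with configurable enrichment near chosen classes, per-base IP and
input coverage, and bait-vs-control spectral counts for S and G2 phases.

Peak placement follows a rejection-sampled density: a candidate position's
relative weight is the largest enrichment weight of any feature class
within the association window of that position, 1 elsewhere, so classes
with weight 1 leave placement uniform and a class with weight w attracts
peaks at w times the background density.  Peak strengths live on the MACS
scale: each peak's IP/input read counts are drawn from a Poisson model and
its strength is -10*log10 of the one-sided binomial-test p-value, so
synthetic strengths are directly comparable to real peak calls.  Paired
conditions ("wild type" vs "helicase depleted") share a configurable
fraction of locations, and shared and unique depleted peaks receive a
configurable positive strength shift.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import FeatureSet, GenomicInterval
from .io import GenomeSequence, PeakTable
from .proteomics import ProteinRecord

__all__ = [
    "FeatureClassSpec",
    "SimulationSpec",
    "make_genome",
    "make_features",
    "plant_peaks",
    "simulate_coverage",
    "simulate_spectral_counts",
    "simulate_study",
]

# condition labels for the five planted peak sets
CONDITIONS = ("pfh1_wt", "cdc20_wt", "cdc20_depleted", "gh2a_wt", "gh2a_depleted")


@dataclass(frozen=True)
class FeatureClassSpec:
    """One annotation class: how many, how long, and how strongly it attracts peaks."""

    name: str
    count: int
    mean_length_bp: int
    weight: float = 1.0  # relative peak-placement density near this class

    def __post_init__(self) -> None:
        if self.count <= 0 or self.mean_length_bp <= 0:
            raise ValueError(f"{self.name}: count and mean length must be > 0")
        if self.weight < 1:
            raise ValueError(f"{self.name}: enrichment weight must be >= 1")


def _default_feature_classes() -> tuple[FeatureClassSpec, ...]:
    # Densities per kb mirror the fission-yeast annotation classes the
    # analysis targets, scaled to the desk-size default genome; weights
    # encode the planted ground truth: strong enrichment at RNA Pol
    # III-like genes, moderate at highly expressed genes and NDRs,
    # none at the remaining classes.
    return (
        FeatureClassSpec("trna_like", 30, 80, weight=20.0),
        FeatureClassSpec("rrna5s_like", 10, 120, weight=20.0),
        FeatureClassSpec("highly_expressed", 60, 1200, weight=5.0),
        FeatureClassSpec("ndr", 120, 150, weight=3.0),
        FeatureClassSpec("origin", 40, 400, weight=1.0),
        FeatureClassSpec("promoter", 120, 200, weight=1.0),
        FeatureClassSpec("ltr", 30, 300, weight=1.0),
        FeatureClassSpec("coding", 150, 1000, weight=1.0),
    )


def _default_n_peaks() -> dict[str, int]:
    # Genome-scale counts from the study conditions (621 helicase, 485/517
    # polymerase, 179/582 damage-mark peaks on a 12.6 Mb genome) scaled by
    # the desk-genome length ratio (~1/21), rounded to round numbers.
    return {
        "pfh1_wt": 120,
        "cdc20_wt": 100,
        "cdc20_depleted": 105,
        "gh2a_wt": 40,
        "gh2a_depleted": 115,
    }


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_chromosomes: int = 3
    chromosome_length_bp: int = 200_000
    gc_block_length_bp: int = 10_000
    gc_range: tuple[float, float] = (0.30, 0.55)
    feature_classes: tuple[FeatureClassSpec, ...] = field(
        default_factory=_default_feature_classes
    )
    n_peaks: dict[str, int] = field(default_factory=_default_n_peaks)
    peak_mean_length_bp: int = 300
    enrichment_window_bp: int = 300
    shared_fraction: float = 0.80  # WT peaks re-used by the depleted condition
    damage_at_fork_fraction: float = 0.71  # damage peaks placed beside polymerase peaks
    depleted_shift: float = 10.0  # strength units (-10*log10 p) added when depleted
    min_peak_separation_bp: int = 50
    coverage_depth: float = 50.0
    coverage_fold: float = 4.0
    # spectral-count model
    n_proteins: int = 100
    frac_interactors: float = 0.20
    bait_mean: float = 30.0
    control_mean: float = 2.0
    n_replicates: int = 2
    g2_depletion: float = 0.40  # G2/S bait-count ratio for true interactors
    deterministic_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length_bp <= 0:
            raise ValueError("genome dimensions must be > 0")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc_range must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0 <= self.damage_at_fork_fraction <= 1:
            raise ValueError("damage_at_fork_fraction must be in [0, 1]")
        if not 0 <= self.g2_depletion <= 1:
            raise ValueError("g2_depletion must be in [0, 1]")
        for cond, n in self.n_peaks.items():
            if n <= 0:
                raise ValueError(f"n_peaks[{cond!r}] must be > 0")

    def chrom_names(self) -> list[str]:
        return [f"chr{'I' * (i + 1)}" for i in range(self.n_chromosomes)]


def full_study_spec(seed: int = 0) -> SimulationSpec:
    """Genome-scale preset mirroring the original study's deposited peak sets.

    Three chromosomes totalling 6 Mb carry the full fission-yeast peak-set
    sizes (621 helicase, 485/517 polymerase, 179/582 damage-mark peaks)
    with the WT/depleted sharing set to the observed 390/485 overlap rate;
    annotation-class counts are scaled to the 6/12.6 genome-length ratio.
    Heavier than the desk-scale default, still well under a minute to
    generate and analyse.
    """
    return SimulationSpec(
        n_chromosomes=3,
        chromosome_length_bp=2_000_000,
        feature_classes=(
            FeatureClassSpec("trna_like", 82, 80, weight=20.0),
            FeatureClassSpec("rrna5s_like", 16, 120, weight=20.0),
            FeatureClassSpec("highly_expressed", 240, 1200, weight=5.0),
            FeatureClassSpec("ndr", 1100, 150, weight=3.0),
            FeatureClassSpec("origin", 355, 400, weight=1.0),
            FeatureClassSpec("promoter", 1550, 200, weight=1.0),
            FeatureClassSpec("ltr", 113, 300, weight=1.0),
            FeatureClassSpec("coding", 2000, 1000, weight=1.0),
        ),
        n_peaks={
            "pfh1_wt": 621,
            "cdc20_wt": 485,
            "cdc20_depleted": 517,
            "gh2a_wt": 179,
            "gh2a_depleted": 582,
        },
        shared_fraction=390 / 485,
        seed=seed,
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> GenomeSequence:
    """Genome with block-wise GC targets drawn uniformly from ``gc_range``.

    Within each block bases are i.i.d. with P(G) = P(C) = gc/2, so the
    empirical block GC is within ~3 binomial standard deviations (well
    under 0.05 for the default 10 kb blocks) of its target.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    for chrom in spec.chrom_names():
        length = spec.chromosome_length_bp
        n_blocks = -(-length // spec.gc_block_length_bp)
        targets = rng.uniform(*spec.gc_range, size=n_blocks)
        gc_per_base = np.repeat(targets, spec.gc_block_length_bp)[:length]
        u = rng.random(length)
        # cumulative thresholds A | C | G | T with P(C)=P(G)=gc/2
        at = (1 - gc_per_base) / 2
        gc_half = gc_per_base / 2
        idx = (
            (u >= at).astype(np.int8)
            + (u >= at + gc_half).astype(np.int8)
            + (u >= at + 2 * gc_half).astype(np.int8)
        )
        sequences[chrom] = _BASES[idx].tobytes().decode("ascii")
    return GenomeSequence(sequences)


def make_features(
    spec: SimulationSpec,
    genome: GenomeSequence,
    rng: np.random.Generator | None = None,
) -> list[FeatureSet]:
    """Place each annotation class uniformly over the genome."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    lengths = genome.lengths
    chroms = list(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    out = []
    for cls in spec.feature_classes:
        intervals = []
        for _ in range(cls.count):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            size = max(10, int(round(rng.normal(cls.mean_length_bp, 0.2 * cls.mean_length_bp))))
            size = min(size, lengths[chrom] - 1)
            start = int(rng.integers(0, lengths[chrom] - size))
            intervals.append(GenomicInterval(chrom, start, start + size, label=cls.name))
        out.append(FeatureSet(cls.name, intervals))
    return out


def _placement_weights(
    spec: SimulationSpec, genome: GenomeSequence, features: Sequence[FeatureSet]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-base placement weight: max class weight within the window, else 1."""
    weight_by_class = {c.name: c.weight for c in spec.feature_classes}
    chroms = genome.chroms
    lengths = genome.lengths
    arrays = {c: np.ones(lengths[c]) for c in chroms}
    w = spec.enrichment_window_bp
    for fs in features:
        weight = weight_by_class.get(fs.name, 1.0)
        if weight <= 1.0:
            continue
        for iv in fs.intervals:
            arr = arrays[iv.chrom]
            lo, hi = max(0, iv.start - w), min(len(arr), iv.end + w)
            np.maximum(arr[lo:hi], weight, out=arr[lo:hi])
    concat = np.concatenate([arrays[c] for c in chroms])
    offsets = np.cumsum([0] + [lengths[c] for c in chroms])
    return chroms, np.cumsum(concat), offsets


def _strength_from_counts(ip: int, inp: int) -> float:
    """MACS-style strength: -10*log10 of a one-sided binomial-test p-value."""
    if ip + inp == 0:
        return 0.0
    p = stats.binomtest(ip, ip + inp, 0.5, alternative="greater").pvalue
    return float(-10 * np.log10(max(p, 1e-300)))


def _draw_locations(
    n: int,
    spec: SimulationSpec,
    cum_weights: np.ndarray,
    chroms: list[str],
    offsets: np.ndarray,
    lengths: Mapping[str, int],
    occupied: list[tuple[str, int, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Sample n non-overlapping peak locations with density prop. to the weights."""
    total = cum_weights[-1]
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place peaks without overlap; genome too crowded")
        flat = int(np.searchsorted(cum_weights, rng.random() * total))
        ci = int(np.searchsorted(offsets, flat, side="right")) - 1
        chrom = chroms[ci]
        center = flat - int(offsets[ci])
        size = max(
            50, int(round(rng.normal(spec.peak_mean_length_bp, 0.2 * spec.peak_mean_length_bp)))
        )
        start = max(0, center - size // 2)
        end = min(lengths[chrom], start + size)
        if end - start < 50:
            continue
        sep = spec.min_peak_separation_bp
        clash = any(
            c == chrom and start - sep < e and o_start - sep < end
            for c, o_start, e in occupied
        )
        if clash:
            continue
        occupied.append((chrom, start, end))
        placed.append((chrom, start, end))
    return placed


def _draw_adjacent(
    n: int,
    anchors: Sequence[tuple[str, int, int]],
    spec: SimulationSpec,
    lengths: Mapping[str, int],
    occupied: list[tuple[str, int, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place n peaks just outside randomly chosen anchor peaks.

    The gap to the anchor is uniform between the minimum peak separation
    and the association window, so the placed peak counts as associated
    with its anchor without overlapping it.
    """
    lo = spec.min_peak_separation_bp + 10
    hi = max(lo + 1, spec.enrichment_window_bp - 20)
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 500 * max(n, 1):
            raise RuntimeError("could not place anchor-adjacent peaks; too crowded")
        chrom, a_start, a_end = anchors[int(rng.integers(len(anchors)))]
        size = max(
            50, int(round(rng.normal(spec.peak_mean_length_bp, 0.2 * spec.peak_mean_length_bp)))
        )
        gap = int(rng.integers(lo, hi))
        if rng.random() < 0.5:
            start = a_end + gap
        else:
            start = a_start - gap - size
        end = start + size
        if start < 0 or end > lengths[chrom]:
            continue
        sep = spec.min_peak_separation_bp
        if any(
            c == chrom and start - sep < e and s - sep < end
            for c, s, e in occupied
        ):
            continue
        occupied.append((chrom, start, end))
        placed.append((chrom, start, end))
    return placed


def plant_peaks(
    spec: SimulationSpec,
    genome: GenomeSequence,
    features: Sequence[FeatureSet],
    rng: np.random.Generator | None = None,
) -> dict[str, PeakTable]:
    """Plant the five condition peak sets with known enrichment and dynamics.

    The helicase set is independent; the polymerase and damage-mark sets
    come in WT/depleted pairs sharing ``shared_fraction`` of the WT
    locations.  A fraction ``damage_at_fork_fraction`` of the damage-mark
    peaks is placed just outside (within the association window of)
    randomly chosen depleted-condition polymerase peaks, emulating DNA
    damage accumulating where forks slow.  Depleted-condition strengths
    get ``depleted_shift`` added (plus small noise), emulating stronger
    fork-slowing and damage signals when the helicase is absent.  Peak
    locations never overlap each other (within or across conditions), so
    planted sharing equals observable overlap exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    chroms, cum_weights, offsets = _placement_weights(spec, genome, features)
    lengths = genome.lengths
    occupied: list[tuple[str, int, int]] = []

    def strengths(n: int) -> np.ndarray:
        folds = rng.lognormal(mean=np.log(3.0), sigma=0.3, size=n)
        ip = rng.poisson(spec.coverage_depth * folds)
        inp = rng.poisson(spec.coverage_depth, size=n)
        return np.array([_strength_from_counts(i, j) for i, j in zip(ip, inp)])

    def draw(n: int) -> list[tuple[str, int, int]]:
        return _draw_locations(
            n, spec, cum_weights, chroms, offsets, lengths, occupied, rng
        )

    noise_sd = max(spec.depleted_shift / 5.0, 0.5)
    tables: dict[str, PeakTable] = {}

    locs = draw(spec.n_peaks["pfh1_wt"])
    s = strengths(len(locs))
    tables["pfh1_wt"] = PeakTable(
        "pfh1_wt",
        [GenomicInterval(c, a, b, float(v)) for (c, a, b), v in zip(locs, s)],
    )

    fork_anchors: list[tuple[str, int, int]] = []
    for mark in ("cdc20", "gh2a"):
        n_wt = spec.n_peaks[f"{mark}_wt"]
        n_dep = spec.n_peaks[f"{mark}_depleted"]
        n_shared = min(int(round(spec.shared_fraction * n_wt)), n_wt, n_dep)

        def draw_pool(n: int) -> list[tuple[str, int, int]]:
            if mark == "gh2a" and fork_anchors and spec.damage_at_fork_fraction > 0:
                k = int(round(spec.damage_at_fork_fraction * n))
                return (
                    _draw_adjacent(k, fork_anchors, spec, lengths, occupied, rng)
                    + draw(n - k)
                )
            return draw(n)

        shared = draw_pool(n_shared)
        wt_only = draw_pool(n_wt - n_shared)
        dep_only = draw_pool(n_dep - n_shared)
        if mark == "cdc20":
            fork_anchors = shared + dep_only  # the depleted-condition locations
        s_shared = strengths(n_shared)
        s_wt_only = strengths(len(wt_only))
        s_dep_only = strengths(len(dep_only)) + spec.depleted_shift
        s_dep_shared = s_shared + spec.depleted_shift + rng.normal(0, noise_sd, n_shared)
        s_dep_shared = np.maximum(s_dep_shared, 0.0)
        wt_ivs = [
            GenomicInterval(c, a, b, float(v))
            for (c, a, b), v in zip(shared + wt_only, np.concatenate([s_shared, s_wt_only]))
        ]
        dep_ivs = [
            GenomicInterval(c, a, b, float(v))
            for (c, a, b), v in zip(
                shared + dep_only, np.concatenate([s_dep_shared, s_dep_only])
            )
        ]
        tables[f"{mark}_wt"] = PeakTable(f"{mark}_wt", wt_ivs)
        tables[f"{mark}_depleted"] = PeakTable(f"{mark}_depleted", dep_ivs)
    return tables


def simulate_coverage(
    genome: GenomeSequence,
    peaks: Sequence[GenomicInterval],
    depth: float,
    fold: float = 4.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-base (IP, input) counts: Poisson(depth) input, fold-enriched IP in peaks."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    ip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for chrom, length in genome.lengths.items():
        lam = np.full(length, depth)
        for peak in peaks:
            if peak.chrom == chrom:
                lam[peak.start : peak.end] = depth * fold
        ip[chrom] = rng.poisson(lam)
        inp[chrom] = rng.poisson(depth, size=length)
    return ip, inp


def simulate_spectral_counts(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord], np.ndarray]:
    """Bait-vs-control spectral counts for S and G2 phases.

    Returns ``(records_s, records_g2, truth)`` where ``truth`` is the
    boolean planted-interactor mask.  True interactors get bait counts far
    above control and SAINT-like scores near 1; non-interactors have
    bait ~ control and scores near 0.  G2 bait counts of true interactors
    are binomially thinned by ``g2_depletion`` (so a factor of 0 makes
    every interactor S-limited).  With ``deterministic_scores`` the scores
    and counts are noise-free, for exact-recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 3)
    n = spec.n_proteins
    k = int(round(spec.frac_interactors * n))
    truth = np.zeros(n, dtype=bool)
    truth[rng.choice(n, size=k, replace=False)] = True
    lengths = rng.integers(100, 1000, size=n)
    pax = rng.lognormal(mean=3.0, sigma=1.0, size=n)

    records_s: list[ProteinRecord] = []
    records_g2: list[ProteinRecord] = []
    for i in range(n):
        pid = f"P{i:04d}"
        if spec.deterministic_scores:
            bait_s = tuple(
                int(round(spec.bait_mean)) if truth[i] else int(round(spec.control_mean))
                for _ in range(spec.n_replicates)
            )
            control = tuple(int(round(spec.control_mean)) for _ in range(spec.n_replicates))
            score = 0.99 if truth[i] else 0.05
            bait_g2 = tuple(
                int(round(c * spec.g2_depletion)) if truth[i] else c for c in bait_s
            )
        else:
            bait_lam = spec.bait_mean if truth[i] else spec.control_mean
            bait_s = tuple(int(v) for v in rng.poisson(bait_lam, size=spec.n_replicates))
            control = tuple(
                int(v) for v in rng.poisson(spec.control_mean, size=spec.n_replicates)
            )
            score = float(rng.beta(50, 2) if truth[i] else rng.beta(2, 50))
            if truth[i]:
                bait_g2 = tuple(int(rng.binomial(c, spec.g2_depletion)) for c in bait_s)
            else:
                bait_g2 = tuple(
                    int(v) for v in rng.poisson(spec.control_mean, size=spec.n_replicates)
                )
        common = dict(length_aa=int(lengths[i]), saint_score=score, pax=float(pax[i]))
        records_s.append(
            ProteinRecord(
                protein_id=pid, spc_bait=bait_s, spc_control=control,
                spc_g2=bait_g2, **common,
            )
        )
        records_g2.append(
            ProteinRecord(
                protein_id=pid, spc_bait=bait_g2, spc_control=control, **common,
            )
        )
    return records_s, records_g2, truth


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic end-to-end run."""

    spec: SimulationSpec
    genome: GenomeSequence
    features: list[FeatureSet]
    peaks: dict[str, PeakTable]
    records_s: list[ProteinRecord]
    records_g2: list[ProteinRecord]
    interactor_truth: np.ndarray


def simulate_study(
    spec: SimulationSpec | None = None, seed: int | None = None
) -> SyntheticStudy:
    """Generate a complete synthetic study from one seed."""
    if spec is None:
        spec = SimulationSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]
    genome = make_genome(spec, rngs[0])
    features = make_features(spec, genome, rngs[1])
    peaks = plant_peaks(spec, genome, features, rngs[2])
    records_s, records_g2, truth = simulate_spectral_counts(spec, rngs[3])
    return SyntheticStudy(spec, genome, features, peaks, records_s, records_g2, truth)
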