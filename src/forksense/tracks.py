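"""Per-base ChIP signal tracks: log2(IP/input) and Hanning smoothing.

The displayed signal is the base-2 logarithm of the IP read count over the
matched input-only count at each position, with a pseudocount added to
both so positions with zero coverage are well defined, smoothed by
convolution with a 1 kb Hanning window.  Edges are handled by renormalising
the truncated kernel, so a constant track stays constant out to its ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["SignalTrack", "log2_ratio", "hanning_smooth", "extract_region", "plot_tracks"]


@dataclass
class SignalTrack:
    """One value per base over [start, start + len(values))."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    @property
    def end(self) -> int:
        return self.start + self.values.size

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)


def log2_ratio(
    ip_counts: np.ndarray,
    input_counts: np.ndarray,
    pseudocount: float = 1.0,
    chrom: str = "",
    start: int = 0,
) -> SignalTrack:
    """log2((ip + pseudocount) / (input + pseudocount)) per base."""
    ip = np.asarray(ip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if ip.shape != inp.shape:
        raise ValueError(f"length mismatch: ip {ip.shape} vs input {inp.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return SignalTrack(chrom, start, np.log2((ip + pseudocount) / (inp + pseudocount)))


def hanning_window(window_bp: int) -> np.ndarray:
    """Unit-sum Hanning kernel of odd length window_bp + 1 (+1 more if even)."""
    m = window_bp + 1
    if m % 2 == 0:
        m += 1
    w = np.hanning(m)
    return w / w.sum()


def hanning_smooth(track: SignalTrack, window_bp: int) -> SignalTrack:
    """Convolve with a unit-sum Hanning window, renormalising at the edges.

    The window length is ``window_bp + 1``, forced odd so the output is
    phase-aligned with the input.  Near the track ends the kernel is
    truncated and its weights renormalised, avoiding padding artifacts.
    """
    if window_bp < 3:
        raise ValueError("window_bp must be >= 3")
    if track.values.size < 3:
        raise ValueError("track too short to smooth (need >= 3 positions)")
    w = hanning_window(window_bp)
    half = (w.size - 1) // 2

    def same_convolve(x: np.ndarray) -> np.ndarray:
        full = np.convolve(x, w, mode="full")
        return full[half : half + x.size]

    num = same_convolve(track.values)
    den = same_convolve(np.ones_like(track.values))
    return SignalTrack(track.chrom, track.start, num / den)


def extract_region(
    source: SignalTrack | Mapping[str, np.ndarray],
    chrom: str,
    center: int,
    half_width: int,
) -> SignalTrack:
    """Slice a 2*half_width window centred on ``center`` out of a track.

    ``source`` is either a SignalTrack or a mapping of chromosome name to a
    full-chromosome per-base array (as produced by the coverage simulator).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    lo, hi = center - half_width, center + half_width
    if isinstance(source, SignalTrack):
        if source.chrom != chrom:
            raise ValueError(f"track is on {source.chrom!r}, requested {chrom!r}")
        if lo < source.start or hi > source.end:
            raise ValueError(
                f"region {chrom}:{lo}-{hi} outside track [{source.start}, {source.end})"
            )
        return SignalTrack(chrom, lo, source.values[lo - source.start : hi - source.start])
    values = source[chrom]
    if lo < 0 or hi > len(values):
        raise ValueError(f"region {chrom}:{lo}-{hi} outside chromosome (len {len(values)})")
    return SignalTrack(chrom, lo, np.asarray(values[lo:hi], dtype=float))


def plot_tracks(
    tracks: Mapping[str, SignalTrack],
    path: str,
    gene: tuple[int, int] | None = None,
    title: str = "",
) -> None:
    """Overlay smoothed signal tracks for one region; optional gene box."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    for label, track in tracks.items():
        ax.plot(track.positions / 1000.0, track.values, lw=1.2, label=label)
    if gene is not None:
        ax.axvspan(gene[0] / 1000.0, gene[1] / 1000.0, color="grey", alpha=0.3)
    ax.set_xlabel("position (kb)")
    ax.set_ylabel("smoothed log2(IP / input)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
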