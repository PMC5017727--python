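"""Analysis-wide configuration and the constants it houses.

The defaults encode the analysis conventions used throughout the package:
peaks are "associated" with a feature when they lie within 300 bp of it
(the ChIP shearing size), damage-mark (γ-H2A) association uses a 5 kb
window because phosphorylated H2A spreads over kilobase-scale domains
around a break, the permutation null uses 1000 GC/length/chromosome-matched
shuffles, interaction confidence is thresholded at a SAINT score of 0.80,
and signal tracks are smoothed with a 1 kb Hanning window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class AnalysisConfig:
    peak_window_bp: int = 300
    damage_window_bp: int = 5000
    n_permutations: int = 1000
    alpha: float = 0.05
    gc_tolerance: float = 0.02
    saint_threshold: float = 0.80
    hanning_bp: int = 1000
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_window_bp <= 0 or self.damage_window_bp <= 0:
            raise ValueError("association windows must be > 0")
        if self.hanning_bp <= 0:
            raise ValueError("hanning_bp must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.gc_tolerance <= 1:
            raise ValueError("gc_tolerance must be in [0, 1]; 1 disables matching")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.saint_threshold <= 1:
            raise ValueError("saint_threshold must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)
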