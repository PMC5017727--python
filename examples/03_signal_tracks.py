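"""Smoothed log2(IP/input) signal around a bound site.

Simulates per-base IP and input coverage with one planted peak, computes
the per-base log2 ratio and smooths it with a 1 kb Hanning window -- the
display used for browsing occupancy around single genes.
"""

import numpy as np

from forksense import GenomeSequence, GenomicInterval, hanning_smooth, log2_ratio
from forksense.simulate import simulate_coverage
from forksense.tracks import extract_region

genome = GenomeSequence({"chrI": "ACGT" * 10_000})  # 40 kb toy chromosome
peak = GenomicInterval("chrI", 19_000, 19_400)
rng = np.random.default_rng(5)
ip, inp = simulate_coverage(genome, [peak], depth=50, fold=4, rng=rng)

region_ip = extract_region(ip, "chrI", center=19_200, half_width=5_000)
region_in = extract_region(inp, "chrI", center=19_200, half_width=5_000)
raw = log2_ratio(region_ip.values, region_in.values, chrom="chrI", start=region_ip.start)
smooth = hanning_smooth(raw, 1000)

argmax = int(smooth.positions[np.argmax(smooth.values)])
print(f"planted peak:        chrI:{peak.start}-{peak.end}")
print(f"smoothed signal max: {smooth.values.max():.2f} at position {argmax}")
print(f"background level:    {np.median(smooth.values):.2f}")
print(
    "\nThe smoothed track peaks inside the planted binding site (~log2(4) = 2"
    "\nbefore smoothing) and sits near 0 elsewhere, as IP and input coverage"
    "\nmatch away from bound regions."
)
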