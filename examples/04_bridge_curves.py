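"""Anatomy of the running-sum bridge curve.

The bridge statistic y(k) = hits(k)/S - k/N measures, at each depth k of
a ranked gene list, how far the target set's rank distribution deviates
from uniform. It always returns to zero at k = N; a ranking that puts all
S target genes first peaks at exactly 1 - S/N.
"""

import numpy as np

from sigbench import average_curves, bridge_curve

genes = [f"G{i:03d}" for i in range(1, 101)]
target = genes[:10]

perfect = bridge_curve(genes, target)
print(f"perfect ranking: peak={perfect.peak:.3f} (= 1 - 10/100)")
print(f"leading edge (x <= 0.02): {perfect.leading_edge_area(0.02):.4f}")

worst = bridge_curve(genes[::-1], target)
print(f"reversed ranking: min={worst.y.min():.3f}, endpoint={worst.y[-1]:.3f}")

rng = np.random.default_rng(0)
null_curves = [
    bridge_curve(list(rng.permutation(genes)), target) for _ in range(200)
]
null_avg = average_curves(null_curves)
print(f"mean |y| of 200 random rankings: {np.abs(null_avg.y).max():.4f}")

# The perfect curve climbs to 0.9 within the first ten ranks and decays
# linearly back to zero; random rankings average out to a flat curve. The
# leading-edge mean over the earliest ranks is the scalar used to compare
# methods: the sharper the early climb, the more target genes a method
# puts at the very top of its signature.
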