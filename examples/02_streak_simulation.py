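"""Bragg + diffuse-streak simulation from Markov stacking of twin layers.

The twin-stacking preset stacks interface layers that grow either as
domain 1 (step a) or as domain 2 (step Ra = b - c/4), switching with
probability alpha.  Sections with l = 4n stay perfectly ordered while
the others develop streaks along a*+b*; Monte-Carlo and transfer-matrix
routes agree point by point.
"""

import numpy as np

from twinstack.stackingsim import (
    extract_section,
    ht_intensity,
    pattern_mc,
    section_grid,
)
from twinstack.synthdata import make_stacking_fixture

model = make_stacking_fixture("twin-stacking", {"alpha": 0.2}, seed=1)
print(f"layers per coherent block: {model.n_layers}, blocks: {model.block_count}, "
      f"switch probability alpha = {model.transition[0, 1]:.2f}")

grid = section_grid([0, 2, 4], [(1, 1, 0), (2, 0, 0)], (1, 1, 0),
                    n_periods=2, samples_per_period=8)
ht = ht_intensity(model, grid)          # exact Markov expectation
mc = pattern_mc(model, grid, seed=7)    # sampled stacking sequences

print("\npeak diffuse power per section (transfer matrix):")
for l in (0, 2, 4):
    peak = extract_section(ht, l, "diffuse").max()
    tag = "ordered (coincidence layer)" if l % 4 == 0 else "streaked"
    print(f"  hk{l}: {peak:12.4g}   {tag}")
print("-> l = 0 and l = 4 carry no diffuse intensity at all: every stacking")
print("   sequence scatters identically there, only l = 2 streaks.")

z = np.abs(mc.total - ht.total) / np.maximum(mc.se, 1e-12)
stochastic = mc.se > 1e-9 * ht.total.max()
print(f"\nMC vs transfer matrix: max |z| over {stochastic.sum()} stochastic "
      f"grid points = {z[stochastic].max():.2f} (should be < ~3)")
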