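"""Weighted sampling without replacement via exponential keys.

Each item receives the key -ln(u)/w; the m smallest keys form a sample
distributed exactly like m sequential cost-proportional draws. Partial
samples over disjoint index ranges merge losslessly, which is how the
kernel parallelizes.
"""

import numpy as np

from sparsekm import merge_partial_samples, sample_without_replacement, stream_rng

weights = [5.0, 1.0, 1.0, 1.0]
reps = 50_000
counts = {}
gen = stream_rng(0, 0)
for _ in range(reps):
    s = sample_without_replacement(weights, 2, gen)
    key = tuple(sorted(int(i) for i in s.indices))
    counts[key] = counts.get(key, 0) + 1

print(f"{reps} draws of 2 items from weights {weights}:")
print("  set   observed   sequential-draw probability")
# exact: P({0,j}) = 5/8*1/3 + 1/8*5/7 for j>0 ; P({i,j}) = 2 * 1/8 * 1/7
exact = {(0, 1): 5 / 24 + 5 / 56, (0, 2): 5 / 24 + 5 / 56, (0, 3): 5 / 24 + 5 / 56,
         (1, 2): 2 / 56, (1, 3): 2 / 56, (2, 3): 2 / 56}
for k in sorted(counts):
    print(f"  {k}  {counts[k] / reps:.4f}     {exact[k]:.4f}")

# merging partial samples over halves equals one pass over the whole array
w = np.abs(np.random.default_rng(1).normal(size=50)) + 0.1
parts = [
    sample_without_replacement(w[:25], 3, stream_rng(7, 0), offset=0),
    sample_without_replacement(w[25:], 3, stream_rng(7, 25), offset=25),
]
merged = merge_partial_samples(parts, 3)
print("\nmerged top-3 indices from two disjoint ranges:", merged.indices.tolist())
print("(identical for any grouping of the ranges across workers)")
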