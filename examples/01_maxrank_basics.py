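"""MaxRank normalization basics.

Builds two rank abundance distributions (RADs) of different richness from
raw count vectors and maps both to the same MaxRank R, making their shapes
directly comparable.
"""

import numpy as np

from radnorm import build_rad, choose_max_R, maxrank_normalize, relative_abundances

# two communities sequenced to different depth and richness
sample_a = build_rad([120, 60, 30, 15, 8, 4, 2, 1], label="A")
sample_b = build_rad([500, 100, 20, 5, 1], label="B")
print(f"sample A: richness {sample_a.richness}, {sample_a.n_individuals} individuals")
print(f"sample B: richness {sample_b.richness}, {sample_b.n_individuals} individuals")

# the largest common MaxRank is the minimum richness in the set
R = choose_max_R([sample_a, sample_b])
print(f"common MaxRank R = {R}")

for rad in (sample_a, sample_b):
    nrad = maxrank_normalize(rad, R, n_reps=100, seed=1)
    with np.printoptions(precision=3):
        print(f"NRAD {rad.label}: {nrad.abundances}  (sum = {nrad.abundances.sum():.6f})")

# normalizing to the full richness reproduces the relative abundances exactly
identity = maxrank_normalize(sample_b, sample_b.richness, n_reps=100, seed=1)
assert np.array_equal(identity.abundances, relative_abundances(sample_b))
print("R = R_s reproduces the original relative abundances exactly")
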