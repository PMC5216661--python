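"""Compute the abundance-weighted exponential-kernel connectivity index.

S_i = sum_{j != i} exp(-alpha * d_ij) * N_j, with alpha = 0.0034 per meter
(a 295 m mean movement distance). A patch 295 m from a single neighbour
with 10 adults scores 10 * exp(-1.003) = 3.67; the index grows with
neighbour abundance and shrinks with distance.
"""

import numpy as np

from patchmeta import (DynamicsConfig, LandscapeConfig, connectivity_index,
                       mean_connectivity, simulate_dataset)

# closed-form toy: one neighbour at the kernel's mean movement distance
d = np.array([[0.0, 295.0], [295.0, 0.0]])
N = np.array([[0.0], [10.0]])
print(f"single-neighbour toy: S = {connectivity_index(d, N, 0.0034)[0, 0]:.4f}")

# per-generation mean connectivity across a synthetic network
patches, surveys = simulate_dataset(LandscapeConfig(seed=1), DynamicsConfig(seed=1))
cm = mean_connectivity(patches, surveys, alpha=0.0034)
cm = cm.merge(patches[["patch_id", "surveyed"]]).query("surveyed")
print("\nmean connectivity of the monitored patches, per generation:")
print(cm.groupby("generation")["connectivity"].agg(["mean", "std"]).round(2))
print("\nSummer connectivity exceeds spring because neighbour abundances "
      "are larger in the summer flight; both are skewed (a few patches sit "
      "close to productive neighbours).")
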