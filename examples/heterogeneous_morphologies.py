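"""Grow realistic cluster shapes and measure their stability.

The preferential-attachment generator places 50 channels on a 20x20 grid
with site weight 1 + ne**alpha (ne = occupied 4-neighbors).  alpha = 0
scatters channels at random; large alpha grows compact blobs.  Compact
clusters carry more oblique contacts per channel and are exponentially
more stable against spontaneous sparks at resting Ca.
"""

import numpy as np

import ryrspark as rs

params = rs.RateParams(sigma=1.0, c0=2.5)


def adjacent_pairs(lat):
    occ = set(lat.sites)
    return sum((x + 1, y) in occ for x, y in occ) + sum((x, y + 1) in occ for x, y in occ)


print(f"{'alpha':>6} {'adj. pairs':>11} {'inter edges':>12} {'mean T (ms)':>12}")
for alpha in (0.0, 5.0, 8.0):
    lats = [rs.grow_preferential(50, 20, 20, alpha, seed=s) for s in range(50)]
    pairs = np.mean([adjacent_pairs(l) for l in lats])
    edges = np.mean([len(rs.lattice_to_graph(l, "oblique").inter_edges) for l in lats])
    spec = rs.GraphSpec(topology="oblique", rows=20, cols=20,
                        n_channels=50, alpha=alpha)
    res = rs.mean_waiting_time(spec, params, n_runs=10, master_seed=21, n_sets=5)
    print(f"{alpha:6.1f} {pairs:11.1f} {edges:12.1f} {res.mean_T:12.4g}")

print("\nEvery simulation run draws a fresh morphology; contact-rich compact")
print("clusters (high alpha) wait far longer before releasing spontaneously.")
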