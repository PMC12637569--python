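"""Watch a quiescent cluster fire a spontaneous Ca spark.

A 10x10 oblique-coupled cluster at c0 = 6 uM idles with 0-2 channels
flickering open until a fluctuation crosses the nc = 5 threshold, after
which calcium-induced calcium release activates nearly all 100 channels
within a millisecond.
"""

import numpy as np

import ryrspark as rs

graph = rs.build_oblique(10, 10)
params = rs.RateParams(sigma=0.5, c0=6.0)

for seed in (11, 12, 13):
    fp = rs.first_passage_time(graph, params, seed=seed)
    traj = rs.simulate_trajectory(graph, params, fp.T + 20.0, seed=seed)
    before = traj.n_open[traj.times < 0.9 * fp.T]
    print(f"seed {seed}: spark at T = {fp.T:9.1f} ms after {fp.n_events:,} events; "
          f"n_open <= {before.max(initial=0)} before the spark, "
          f"{traj.n_open.max()} of 100 channels open after")

print("\nT is the waiting time from an all-closed cluster to the first spark;")
print("its reciprocal is the spontaneous spark frequency of this release site.")
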