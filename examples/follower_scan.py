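"""Follower validation scan for the one-boundary VCP metric.

Starting from an unreduced presentation of a random lattice, the Follower
walks the straight S6 segment to the start's Selling-reduced image and
records the distance from each sample's lattice to the endpoint lattice.
The endpoints must read zero (both present the endpoint's lattice) and the
trace must never jump faster than the evaluated points move (the candidate
maps are isometries, so the metric is 1-Lipschitz).
"""

import numpy as np

from s6lattice import follower_qc, follower_trace, random_reduced, unreduce_random

rng = np.random.default_rng(42)
base = random_reduced(1, rng)[0]
start = unreduce_random(base, steps=2, rng=rng)

trace = follower_trace(start, n_samples=200, strategy="vcp1")
qc = follower_qc(trace)

print("start (unreduced S6):", np.round(start, 3))
print("endpoint (reduced)  :", np.round(trace.end, 3))
print(f"distance at t=0 / t=1 : {qc.endpoint_values[0]:.3g} / {qc.endpoint_values[1]:.3g} Å²")
print(f"peak distance along scan: {trace.distances.max():.4f} Å² at t={trace.t[np.argmax(trace.distances)]:.3f}")
print(f"max jump {qc.max_jump:.4f} Å² (Lipschitz excess {qc.max_jump_excess:.3g}; ≤ 0 means OK)")
print(f"slope breaks: {qc.n_slope_breaks} (boundary crossings show as kinks, not jumps)")
print("quality control:", "PASS" if qc.all_ok else "FAIL")
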