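"""Sieve-based agglomerative clustering of trajectory frames.

Frames from two distinct conformer families are clustered on pairwise
best-fit RMSD with average linkage (cutoff 2.0 A, sieve 5): every fifth
frame is clustered directly and the rest join the nearest cluster medoid.
"""

import numpy as np

import polsensor as ps

rng = np.random.default_rng(3)
base = ps.make_two_state_trajectory(ps.TwoStateParams(n_frames=40, seed=3))
site = base.metadata["sitemap"]

# construct two conformer families: family B rearranges the sensor region
coords = base.coords.copy()
family = rng.random(40) < 0.5
moved = [site.atom_index(base.topology, "sensor", nm) for nm in ("CB", "CG")]
for f in range(40):
    coords[f] = base.coords[0] + rng.normal(0, 0.05, coords[f].shape)
    if family[f]:
        coords[f, moved] += np.array([12.0, -8.0, 10.0])
traj = ps.Trajectory(base.topology, coords, frame_interval=12.5)

result = ps.cluster_frames(traj, ps.AtomSelector(), cutoff=2.0, sieve=5)
print(f"clusters found:        {result.n_clusters}")
print(f"cluster sizes:         {np.bincount(result.assignments).tolist()}")
print(f"true family sizes:     {[int((~family).sum()), int(family.sum())]}")
print(f"medoid frames:         {result.representatives}")
print(f"directly clustered:    every {5}th frame "
      f"({len(result.sieved_frames)} of {traj.n_frames})")
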