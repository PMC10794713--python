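"""Ring-packing order parameter on a synthetic rigid-ring trajectory.

Eight rings diffuse in a 50 nm box (initial pairwise spacing >= 16 nm);
halfway through, three of them are scripted into a mutually contacting
cluster with orthogonal normals.  The analysis enumerates contact-graph
triangles per frame and scores each with p = |n1 . (n2 x n3)|: p -> 1
means cube-corner (orthogonal) packing, p -> 0 coplanar packing.
"""

from capsidmorph.rings import classify_packing, frame_summary
from capsidmorph.synthetic import TrajectorySpec, gen_ring_trajectory

spec = TrajectorySpec(cluster_mode="orthogonal", cluster_onset=0.5, n_frames=60, seed=1)
traj = gen_ring_trajectory(spec)
summary = frame_summary(traj, threshold=12.0)

print("frame  contacts  triplets   max_p")
for row in summary.itertuples():
    if row.frame % 10 == 0 or row.frame == 59:
        max_p = f"{row.max_p:.3f}" if row.n_triplets else "    -"
        print(f"{row.frame:>5}{row.n_contacts:>10}{row.n_triplets:>10}{max_p:>8}")

final = summary.iloc[-1]
print(
    f"\nFinal frame: max triplet p = {final.max_p:.3f} -> "
    f"{classify_packing(final.max_p)} packing."
)
print("Before frame 30 the rings are dispersed (no triplets); after the scripted")
print("clustering a persistent triplet holds p near 1, the cube-corner signature.")
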