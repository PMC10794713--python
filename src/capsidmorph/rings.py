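"""Ring-packing analysis of rigid-ring trajectories.

Octameric coat-protein rings diffusing in solution occasionally meet and
form contacts.  For every trajectory frame we build a contact graph over
ring centers, enumerate fully connected triplets (triangles), and score
each triplet's packing with the orientation order parameter

    p = |n1 · (n2 × n3)|

over the three unit ring normals: p = 1 for mutually orthogonal rings
(the corner of a cube), p = 0 for coplanar ring orientations.  p is
invariant under permutation of the rings, under flipping any normal
(ring normals have no preferred sign), and under global rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RingPose",
    "order_parameter",
    "detect_contacts",
    "find_triplets",
    "triplet_time_series",
    "frame_summary",
    "classify_packing",
    "normal_from_points",
    "DEFAULT_CONTACT_THRESHOLD",
]

#: Default center-center contact cutoff (nm), ~1.1x the ring diameter.
DEFAULT_CONTACT_THRESHOLD = 12.0

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class RingPose:
    """Position and orientation of one rigid ring in one frame."""

    ring_id: int
    center: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"ring {self.ring_id}: normal must be unit length, |n| = {np.linalg.norm(n):.6g}"
            )


def order_parameter(n1, n2, n3, normalize: bool = False) -> float:
    """Packing order parameter p = |n1 · (n2 × n3)| of three unit normals.

    With ``normalize=True`` inputs are normalized first; otherwise non-unit
    inputs raise.  The result lies in [0, 1] (Hadamard bound for unit
    vectors); tiny floating excursions above 1 are clipped.
    """
    vecs = [np.asarray(v, dtype=float) for v in (n1, n2, n3)]
    for i, v in enumerate(vecs):
        norm = np.linalg.norm(v)
        if normalize:
            if norm == 0:
                raise ValueError(f"normal {i + 1} is the zero vector")
            vecs[i] = v / norm
        elif abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"normal {i + 1} is not unit length (|n| = {norm:.6g}); "
                "pass normalize=True to normalize first"
            )
    p = abs(float(np.dot(vecs[0], np.cross(vecs[1], vecs[2]))))
    return min(p, 1.0)


def _poses_from_frame(frame: pd.DataFrame) -> list[RingPose]:
    return [
        RingPose(
            ring_id=int(r.ring_id),
            center=(r.cx, r.cy, r.cz),
            normal=(r.nx, r.ny, r.nz),
        )
        for r in frame.itertuples()
    ]


def detect_contacts(
    poses: Sequence[RingPose], threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> nx.Graph:
    """Contact graph: edge (i, j) iff center distance <= threshold (nm)."""
    if len(poses) < 1:
        raise ValueError("need at least one ring pose")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ids = [p.ring_id for p in poses]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ring_ids in frame: {sorted(ids)}")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(ids)
    if len(poses) > 1:
        centers = np.array([p.center for p in poses], dtype=float)
        dmat = squareform(pdist(centers))
        ii, jj = np.nonzero(np.triu(dmat <= threshold, k=1))
        g.add_edges_from((ids[i], ids[j]) for i, j in zip(ii, jj))
    return g


def find_triplets(g: nx.Graph) -> list[tuple[int, int, int]]:
    """All triangles of the contact graph, each once with sorted ids.

    Enumerates each edge and intersects the endpoint neighborhoods, keeping
    the triangle only when the third node is largest — reports each triangle
    exactly once.
    """
    triangles: list[tuple[int, int, int]] = []
    adj = {u: set(g.neighbors(u)) for u in g.nodes}
    for u, v in g.edges:
        a, b = sorted((u, v))
        for w in adj[a] & adj[b]:
            if w > b:
                triangles.append((a, b, w))
    return sorted(triangles)


def triplet_time_series(
    traj: pd.DataFrame, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> pd.DataFrame:
    """Per-frame triplet records over a trajectory table.

    ``traj`` uses the trajectory TSV dialect (columns frame, time, ring_id,
    cx, cy, cz, nx, ny, nz).  For every frame, every triangle of the contact
    graph yields one record with p computed from the three ring normals.
    Frames with fewer than three rings contribute no records.

    Returns a DataFrame with columns frame, time, i, j, k, p ordered by
    (frame, i, j, k).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    records = []
    for frame_idx, frame in traj.groupby("frame", sort=True):
        poses = _poses_from_frame(frame)
        if len(poses) < 3:
            continue
        normals = {p.ring_id: np.asarray(p.normal) for p in poses}
        time = float(frame["time"].iloc[0])
        g = detect_contacts(poses, threshold)
        for i, j, k in find_triplets(g):
            records.append(
                {
                    "frame": int(frame_idx),
                    "time": time,
                    "i": i,
                    "j": j,
                    "k": k,
                    "p": order_parameter(normals[i], normals[j], normals[k]),
                }
            )
    return pd.DataFrame(records, columns=["frame", "time", "i", "j", "k", "p"])


def frame_summary(
    traj: pd.DataFrame, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> pd.DataFrame:
    """Per-frame contact/triplet summary for plotting time evolution.

    Columns: frame, time, n_contacts, n_triplets, max_p, mean_p (NaN where a
    frame has no triplets).
    """
    trips = triplet_time_series(traj, threshold)
    rows = []
    for frame_idx, frame in traj.groupby("frame", sort=True):
        poses = _poses_from_frame(frame)
        g = detect_contacts(poses, threshold)
        sub = trips[trips["frame"] == frame_idx]
        rows.append(
            {
                "frame": int(frame_idx),
                "time": float(frame["time"].iloc[0]),
                "n_contacts": g.number_of_edges(),
                "n_triplets": len(sub),
                "max_p": sub["p"].max() if len(sub) else np.nan,
                "mean_p": sub["p"].mean() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def classify_packing(p: float, lo: float = 0.2, hi: float = 0.8) -> str:
    """Label a p value as planar (p <= lo), orthogonal (p >= hi) or intermediate."""
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if not (0 <= p <= 1):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p <= lo:
        return "planar"
    if p >= hi:
        return "orthogonal"
    return "intermediate"


def normal_from_points(points: Iterable[Sequence[float]]) -> np.ndarray:
    """Best-fit plane normal of ring subunit positions (least squares).

    For poses lacking explicit normals: the unit normal of the plane through
    the centroid minimizing squared distances (smallest-singular-vector of
    the centered coordinates).  Sign is arbitrary; p is sign-invariant.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least three points to fit a plane")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]
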