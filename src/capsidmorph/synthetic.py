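"""Seed-controlled synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure its downstream analysis
assumes, so the whole pipeline runs without any external downloads:

* rigid-ring trajectories (random-walk diffusion of eight rings in a
  50 nm box, placed with >= 16 nm initial pairwise spacing, optionally
  forming a scripted planar or orthogonal three-ring cluster) standing in
  for coarse-grained MD trajectories;
* multi-component Gaussian filament-length mixtures (fused filaments
  yield peaks at integer multiples of the unit length);
* sigmoidal melt curves whose first-derivative minimum sits at a known
  true Tm;
* two-replicate read-alignment tables over a small CDS reference set
  with configurable composition, MAPQ mix and 3'-end anchoring bias.

The generators produce kinematically plausible data, not physics: the
force field, solvent and image formation behind the real experiments are
deliberately out of scope.  All randomness flows through one integer
seed per spec; replicate seeds derive as seed + replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .morphometry import LengthSample
from .rnaquant import ALN_COLUMNS, RNA_CLASSES, ReferenceSet
from .stability import MeltCurve

__all__ = [
    "TrajectorySpec",
    "LengthMixtureSpec",
    "MeltCurveSpec",
    "AlignmentSimSpec",
    "gen_ring_trajectory",
    "gen_length_sample",
    "gen_melt_curve",
    "gen_read_alignments",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_alignments_sam",
    "PlacementError",
]

#: Ring diameter default (nm): the initial spacing is 1.5 ring diameters,
#: so with 16 nm spacing the diameter is 16/1.5.
DEFAULT_RING_DIAMETER = 16.0 / 1.5


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the spacing constraint."""


# ---------------------------------------------------------------------------
# Ring trajectories


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a synthetic rigid-ring trajectory.

    Defaults mirror the simulated study conditions: 8 rings in a 50 nm
    cubic box, >= 16 nm initial pairwise spacing.
    """

    n_rings: int = 8
    box_edge: float = 50.0  # nm
    min_spacing: float = 16.0  # nm
    ring_diameter: float = DEFAULT_RING_DIAMETER  # nm
    cluster_mode: str = "none"  # none | planar | orthogonal
    cluster_onset: float = 0.5  # fraction of the trajectory
    n_frames: int = 100
    seed: int = 0
    step_sd: float = 0.5  # nm per frame, diffusive step
    rot_sd: float = 0.05  # rad per frame, orientational diffusion
    cluster_noise: float = 0.01  # orientation noise of the scripted cluster

    def __post_init__(self) -> None:
        if self.cluster_mode not in ("none", "planar", "orthogonal"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")
        if self.cluster_mode != "none" and self.n_rings < 3:
            raise ValueError("clustered trajectories need at least 3 rings")
        if not self.min_spacing < self.box_edge:
            raise ValueError("min_spacing must be smaller than box_edge")
        if self.ring_diameter <= 0:
            raise ValueError("ring_diameter must be > 0")
        if not 0 <= self.cluster_onset <= 1:
            raise ValueError("cluster_onset must lie in [0, 1]")
        if self.n_rings < 1 or self.n_frames < 1:
            raise ValueError("n_rings and n_frames must be >= 1")


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_centers(spec: TrajectorySpec, rng: np.random.Generator, attempts: int = 20000) -> np.ndarray:
    """Rejection-sample initial centers with pairwise spacing >= min_spacing."""
    margin = spec.ring_diameter / 2
    lo, hi = margin, spec.box_edge - margin
    centers: list[np.ndarray] = []
    tries = 0
    point_tries = 0
    while len(centers) < spec.n_rings:
        if tries >= attempts:
            raise PlacementError(
                f"could not place {spec.n_rings} rings with pairwise spacing >= "
                f"{spec.min_spacing} nm inside a {spec.box_edge} nm box after {attempts} attempts"
            )
        cand = rng.uniform(lo, hi, size=3)
        tries += 1
        point_tries += 1
        if all(np.linalg.norm(cand - c) >= spec.min_spacing for c in centers):
            centers.append(cand)
            point_tries = 0
        elif point_tries >= 2000:  # blocked configuration: restart from scratch
            centers.clear()
            point_tries = 0
    return np.array(centers)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates at the walls (no periodic wrap)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)  # guards pathological double crossings


def _small_rotation(rng: np.random.Generator, normals: np.ndarray, sd: float) -> np.ndarray:
    """Perturb each unit normal by a small random tangential kick."""
    kick = rng.normal(scale=sd, size=normals.shape)
    kick -= (kick * normals).sum(axis=1, keepdims=True) * normals
    out = normals + kick
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _cluster_geometry(spec: TrajectorySpec, rng: np.random.Generator):
    """Scripted triplet: centers in mutual contact, normals per cluster mode."""
    center = np.full(3, spec.box_edge / 2.0)
    side = min(spec.ring_diameter * 1.05, 11.0)  # mutual contact under ~12 nm cutoffs
    # equilateral triangle in the xy-plane around the box center
    angles = np.deg2rad([90.0, 210.0, 330.0])
    r = side / np.sqrt(3.0)
    centers = center + np.stack(
        [r * np.cos(angles), r * np.sin(angles), np.zeros(3)], axis=1
    )
    if spec.cluster_mode == "orthogonal":
        normals = np.eye(3)
    else:  # planar: distinct in-plane azimuths
        az = np.deg2rad([0.0, 60.0, 120.0])
        normals = np.stack([np.cos(az), np.sin(az), np.zeros(3)], axis=1)
    return centers, normals


def gen_ring_trajectory(spec: TrajectorySpec) -> pd.DataFrame:
    """Generate a rigid-ring trajectory table.

    Columns: frame, time, ring_id, cx, cy, cz, nx, ny, nz (nm; unit
    normals; time in frame units).  Frame 0 satisfies the pairwise-spacing
    constraint; rings random-walk inside the box with reflecting walls.  In
    ``planar``/``orthogonal`` mode, rings 0-2 snap to a scripted mutually
    contacting cluster from ``cluster_onset`` onward and stay there (small
    orientation noise, renormalized), giving a persistent triplet whose
    order parameter is ~0 (planar) or ~1 (orthogonal).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    normals = _random_unit_vectors(rng, spec.n_rings)
    margin = spec.ring_diameter / 2
    onset_frame = int(np.ceil(spec.cluster_onset * (spec.n_frames - 1))) if spec.n_frames > 1 else 0
    cluster_centers = cluster_normals = None
    if spec.cluster_mode != "none":
        cluster_centers, cluster_normals = _cluster_geometry(spec, rng)

    rows = []
    for frame in range(spec.n_frames):
        if frame > 0:
            centers = _reflect(
                centers + rng.normal(scale=spec.step_sd, size=centers.shape),
                margin,
                spec.box_edge - margin,
            )
            normals = _small_rotation(rng, normals, spec.rot_sd)
        if cluster_centers is not None and frame >= onset_frame:
            centers[:3] = cluster_centers
            jitter = rng.normal(scale=spec.cluster_noise, size=(3, 3))
            n = cluster_normals + jitter
            normals[:3] = n / np.linalg.norm(n, axis=1, keepdims=True)
            # keep free rings clear of the scripted cluster so the persistent
            # triplet is not contaminated by chance contacts
            box_center = np.full(3, spec.box_edge / 2.0)
            for ring_id in range(3, spec.n_rings):
                rel = centers[ring_id] - box_center
                dist = np.linalg.norm(rel)
                if dist < 19.0:
                    direction = rel / dist if dist > 0 else np.array([1.0, 0.0, 0.0])
                    centers[ring_id] = _reflect(
                        box_center + direction * 19.0, margin, spec.box_edge - margin
                    )
        for ring_id in range(spec.n_rings):
            cx, cy, cz = centers[ring_id]
            nx, ny, nz = normals[ring_id]
            rows.append((frame, float(frame), ring_id, cx, cy, cz, nx, ny, nz))
    return pd.DataFrame(
        rows, columns=["frame", "time", "ring_id", "cx", "cy", "cz", "nx", "ny", "nz"]
    )


def write_trajectory_tsv(traj: pd.DataFrame, path: Union[str, Path]) -> None:
    traj.to_csv(path, sep="\t", index=False)


def read_trajectory_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Length mixtures


@dataclass(frozen=True)
class LengthMixtureSpec:
    """Gaussian mixture of filament lengths (weights, means and sds in nm)."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mean, sd)
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("components list must not be empty")
        weights = [c[0] for c in self.components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {sum(weights)}")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("all component means must be > 0")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("all component sds must be > 0")
        object.__setattr__(self, "components", tuple(tuple(c) for c in self.components))


def gen_length_sample(spec: LengthMixtureSpec) -> LengthSample:
    """Draw filament lengths from the mixture, truncated at zero (resampled)."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[0] for c in spec.components])
    counts = rng.multinomial(spec.n_samples, weights)
    draws = []
    for (w, mean, sd), n in zip(spec.components, counts):
        vals = rng.normal(mean, sd, size=n)
        while np.any(vals <= 0):  # truncate at zero by redrawing
            bad = vals <= 0
            vals[bad] = rng.normal(mean, sd, size=bad.sum())
        draws.append(vals)
    lengths = np.concatenate(draws) if draws else np.empty(0)
    rng.shuffle(lengths)
    return LengthSample(lengths=lengths, label=f"mixture(seed={spec.seed})")


# ---------------------------------------------------------------------------
# Melt curves


@dataclass(frozen=True)
class MeltCurveSpec:
    """Sigmoidal melt curve with a known true Tm.

    The transition is a *decreasing* logistic in temperature, so the first
    derivative has its extremum as a minimum at ``tm_true`` — matching the
    derivative-minimum extraction convention.  The default grid spans the
    measured 25-95 degC ramp at 1 degC steps.
    """

    tm_true: float = 55.0
    t_range: tuple[float, float, float] = (25.0, 95.0, 1.0)  # start, stop, step
    amplitude: float = 1000.0
    slope: float = 0.5  # 1/degC logistic rate
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.t_range
        if step <= 0 or stop <= start:
            raise ValueError("t_range must be ascending with positive step")
        if not (start < self.tm_true < stop):
            raise ValueError("tm_true must lie strictly inside t_range")


def gen_melt_curve(spec: MeltCurveSpec) -> MeltCurve:
    """Generate a noisy decreasing-sigmoid melt curve."""
    start, stop, step = spec.t_range
    temps = np.arange(start, stop + step / 2, step)
    fluor = spec.amplitude / (1.0 + np.exp(spec.slope * (temps - spec.tm_true)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fluor = fluor + rng.normal(scale=spec.noise_sd, size=fluor.shape)
    return MeltCurve(temperatures=temps, fluorescence=fluor)


# ---------------------------------------------------------------------------
# Read alignments


@dataclass(frozen=True)
class AlignmentSimSpec:
    """Two-replicate synthetic alignment sets over a small CDS universe.

    references: (ref_id, length nt, class) with class in CP/p97/rRNA/other.
    composition: per-reference read fraction (sums to 1).
    three_prime_bias: fraction of reads anchored at the reference 3' end.
    mapq_high_fraction: fraction of reads assigned MAPQ 60 (rest uniform 0-59).
    """

    references: tuple[tuple[str, int, str], ...]
    composition: tuple[float, ...]
    read_length_dist: tuple[float, float] = (500.0, 100.0)  # mean, sd (nt)
    three_prime_bias: float = 1.0
    n_reads: int = 1000  # per replicate
    n_replicates: int = 2
    mapq_high_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.references) == 0:
            raise ValueError("need at least one reference")
        if len(self.composition) != len(self.references):
            raise ValueError("composition must align with references")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {sum(self.composition)}")
        for ref_id, length, cls in self.references:
            if length <= 0:
                raise ValueError(f"reference {ref_id!r} length must be > 0")
            if cls not in RNA_CLASSES:
                raise ValueError(f"unknown class {cls!r} for reference {ref_id!r}")
        if self.read_length_dist[0] <= 0:
            raise ValueError("read length mean must be > 0")
        for frac in (self.three_prime_bias, self.mapq_high_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "references", tuple(tuple(r) for r in self.references))
        object.__setattr__(self, "composition", tuple(self.composition))

    def reference_set(self) -> ReferenceSet:
        return ReferenceSet(
            lengths={r[0]: int(r[1]) for r in self.references},
            classes={r[0]: r[2] for r in self.references},
        )


def _simulate_replicate(spec: AlignmentSimSpec, rep: int) -> pd.DataFrame:
    rng = np.random.default_rng(spec.seed + rep)  # replicate seeds: seed + index
    ids = [r[0] for r in spec.references]
    lengths = {r[0]: int(r[1]) for r in spec.references}
    ref_choice = rng.choice(len(ids), size=spec.n_reads, p=np.array(spec.composition))
    mean_len, sd_len = spec.read_length_dist
    rows = []
    for i in range(spec.n_reads):
        ref_id = ids[int(ref_choice[i])]
        ref_len = lengths[ref_id]
        read_len = int(round(rng.normal(mean_len, sd_len)))
        read_len = max(1, min(read_len, ref_len))  # clip to full reference
        if rng.random() < spec.three_prime_bias:
            offset = int(rng.integers(0, min(50, ref_len - read_len + 1)))
            end = ref_len - offset
            start = end - read_len
        else:
            start = int(rng.integers(0, ref_len - read_len + 1))
            end = start + read_len
        mapq = 60 if rng.random() < spec.mapq_high_fraction else int(rng.integers(0, 60))
        rows.append((f"rep{rep}_read{i}", ref_id, start, end, mapq))
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def gen_read_alignments(spec: AlignmentSimSpec) -> list[pd.DataFrame]:
    """Per-replicate alignment tables (0-based half-open coordinates)."""
    return [_simulate_replicate(spec, rep) for rep in range(spec.n_replicates)]


def write_alignments_sam(
    alns: pd.DataFrame, refs: ReferenceSet, path: Union[str, Path]
) -> None:
    """Write an alignment table as minimal single-end SAM with @SQ headers.

    FLAG 0 for every record (no unmapped or reverse-strand records in the
    data model); CIGAR is a single match run; SEQ/QUAL omitted.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref_id, length in refs.lengths.items():
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{length}\n")
        for row in alns.itertuples():
            span = int(row.end) - int(row.start)
            fh.write(
                f"{row.read_id}\t0\t{row.ref_id}\t{int(row.start) + 1}\t{int(row.mapq)}\t"
                f"{span}M\t*\t0\t0\t*\t*\n"
            )
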