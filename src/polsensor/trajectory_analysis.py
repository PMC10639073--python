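"""Per-frame descriptor series, state populations and frame clustering.

A :class:`Trajectory` stores one topology (a :class:`Structure` giving the
atom roster and addressing) plus an ``(n_frames, n_atoms, 3)`` coordinate
array, which keeps descriptor series over tens of thousands of frames
vectorised and makes the constant-roster invariant structural.  Defaults
mirror the analysis protocol the descriptors were designed for: frames saved
every 2.5 ps, the first 30 ns of each production run discarded as extended
equilibration, measurements extracted every 12.5 ps of the final 100 ns, and
frame clustering by hierarchical agglomeration with a sieve of 5 and a
2.0 Å RMSD cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InconsistentTrajectoryError
from .sitemap import SiteMap
from .structure_io import AtomSelector, Structure, read_pdb, select_atoms
from .superposition import kabsch_fit

__all__ = [
    "Trajectory", "DescriptorSeries", "StateSummary", "Density2D",
    "ClusterResult",
    "load_trajectory", "trajectory_from_structures",
    "trim_and_subsample", "descriptor_series", "state_populations",
    "density2d", "cluster_frames", "replica_summary",
    "frames_per_system", "total_sampling_us", "equilibration_total_ns",
    "DEFAULT_EQUILIBRATION_SCHEDULE_NS",
]

DEFAULT_FRAME_INTERVAL_PS = 2.5
DEFAULT_SKIP_NS = 30.0
DEFAULT_STRIDE_PS = 12.5


@dataclass
class Trajectory:
    """Constant-roster multi-frame coordinate set with time metadata."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float  # ps
    replica_id: str = "r1"
    t0: float = 0.0  # ps
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise InconsistentTrajectoryError(
                f"coordinate columns ({self.coords.shape[1]}) do not match the "
                f"topology roster ({len(self.topology)} atoms)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


def trajectory_from_structures(frames: list[Structure], frame_interval: float,
                               replica_id: str = "r1", t0: float = 0.0) -> Trajectory:
    """Build a Trajectory from per-frame Structures, enforcing one roster."""
    if not frames:
        raise InconsistentTrajectoryError("trajectory needs at least one frame")
    roster = frames[0].roster()
    for k, f in enumerate(frames[1:], start=1):
        if f.roster() != roster:
            raise InconsistentTrajectoryError(
                f"frame {k} atom roster differs from frame 0")
    coords = np.stack([f.coords for f in frames])
    return Trajectory(frames[0], coords, frame_interval, replica_id, t0)


def load_trajectory(source, frame_interval: float, replica_id: str = "r1",
                    t0: float = 0.0) -> Trajectory:
    """Load frames from a multi-model PDB stream (str) or a per-frame
    coordinate table (DataFrame with columns frame, atom_id, x, y, z plus a
    ``topology`` passed separately is handled by
    :func:`trajectory_from_table`).  Times are t0 + k·frame_interval."""
    if isinstance(source, str):
        frames = read_pdb(source)
        return trajectory_from_structures(frames, frame_interval, replica_id, t0)
    if isinstance(source, (list, tuple)):
        return trajectory_from_structures(list(source), frame_interval, replica_id, t0)
    raise TypeError("source must be PDB text or a list of Structures")


def trajectory_from_table(table, topology: Structure, frame_interval: float,
                          replica_id: str = "r1", t0: float = 0.0) -> Trajectory:
    """Plain-text alternative input: rows (frame, atom_id, x, y, z) where
    atom_id is the 0-based index into the topology's atom order."""
    import pandas as pd

    df = pd.DataFrame(table) if not hasattr(table, "pivot") else table
    n_atoms = len(topology)
    frames = sorted(df["frame"].unique())
    coords = np.empty((len(frames), n_atoms, 3))
    for fi, fr in enumerate(frames):
        sub = df[df["frame"] == fr].sort_values("atom_id")
        if len(sub) != n_atoms:
            raise InconsistentTrajectoryError(
                f"frame {fr} has {len(sub)} atoms, topology has {n_atoms}")
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(topology, coords, frame_interval, replica_id, t0)


def trim_and_subsample(traj: Trajectory, skip_ns: float = DEFAULT_SKIP_NS,
                       every_ps: float = DEFAULT_STRIDE_PS) -> Trajectory:
    """Drop frames before ``skip_ns`` and keep one frame per ``every_ps``.

    ``every_ps`` must be an integer multiple of the storage interval — frames
    are selected, never interpolated — and the skip must leave at least one
    frame.
    """
    ratio = every_ps / traj.frame_interval
    stride = round(ratio)
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise ValueError(
            f"stride {every_ps} ps is not an integer multiple of the "
            f"frame interval {traj.frame_interval} ps")
    skip_ps = skip_ns * 1000.0
    rel = traj.times - traj.t0
    keep = np.where(rel >= skip_ps - 1e-9)[0]
    if keep.size == 0:
        raise ValueError(f"skip {skip_ns} ns discards the whole trajectory")
    keep = keep[::stride]
    return Trajectory(traj.topology, traj.coords[keep],
                      every_ps, traj.replica_id, float(traj.times[keep[0]]),
                      dict(traj.metadata))


@dataclass
class DescriptorSeries:
    replica_id: str
    times: np.ndarray  # ps
    values: np.ndarray
    kind: str  # sensor_angle | gate_distance | catalytic_gap

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


_SERIES_ATOMS = {
    # kind -> ((role, atom_name), ...) in the order the geometry needs
    "sensor_angle": (("sensor", "CA"), ("sensor", "CG"), ("nucleotide", "O2B")),
    "gate_distance": (("steric_gate", "CD1"), ("nucleotide", "C2'")),
    "catalytic_gap": (("catalytic_1", "CA"), ("steric_gate", "OH")),
}


def _resolve_series_indices(traj: Trajectory, site: SiteMap, kind: str) -> list[int]:
    spec = _SERIES_ATOMS[kind]
    idx = []
    for role, name in spec:
        if kind == "sensor_angle" and name == "CG":
            addr = site.address(role)
            name = "CG" if traj.topology.has_atom(addr.chain, addr.res_num, "CG") else "CG1"
        idx.append(site.atom_index(traj.topology, role, name))
    return idx


def descriptor_series(traj: Trajectory, site: SiteMap, kind: str) -> DescriptorSeries:
    """One descriptor value per frame, vectorised over the coordinate array.

    Values agree with per-frame evaluation by the descriptors module.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if kind not in _SERIES_ATOMS:
        raise KeyError(f"unknown descriptor kind {kind!r}")
    idx = _resolve_series_indices(traj, site, kind)
    if kind == "sensor_angle":
        ca, cg, o2b = (traj.coords[:, i, :] for i in idx)
        u = ca - cg
        v = o2b - cg
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        values = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    else:
        a, b = (traj.coords[:, i, :] for i in idx)
        values = np.linalg.norm(a - b, axis=1)
    return DescriptorSeries(traj.replica_id, traj.times, values, kind)


@dataclass
class StateSummary:
    n_frames: int
    p_locked: float
    p_unlocked: float
    locked_mean: float
    locked_sd: float
    unlocked_mean: float
    unlocked_sd: float
    threshold: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_frames", "p_locked", "p_unlocked", "locked_mean", "locked_sd",
            "unlocked_mean", "unlocked_sd", "threshold")}


def state_populations(series: DescriptorSeries, threshold: float = 140.0) -> StateSummary:
    """Fraction of frames in the locked (value ≥ threshold) and unlocked
    states, with per-state mean/SD (NaN for an unpopulated state)."""
    if len(series) == 0:
        raise ValueError("empty descriptor series")
    v = series.values
    locked = v >= threshold

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x))

    lm, ls = _stats(v[locked])
    um, us = _stats(v[~locked])
    p = float(np.mean(locked))
    return StateSummary(len(v), p, 1.0 - p, lm, ls, um, us, threshold)


@dataclass
class Density2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_clipped: int = 0

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


def density2d(x: DescriptorSeries, y: DescriptorSeries,
              x_edges, y_edges) -> Density2D:
    """2D occupancy histogram of two aligned descriptor series (e.g. gate
    distance vs sensor angle).  Out-of-range values are clipped into the edge
    bins and counted, so Σcounts always equals the frame count."""
    if len(x) != len(y) or not np.array_equal(x.times, y.times):
        raise ValueError("series are not frame-aligned")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    eps_x = 1e-9 * max(1.0, abs(x_edges[-1]))
    eps_y = 1e-9 * max(1.0, abs(y_edges[-1]))
    xv = np.clip(x.values, x_edges[0], x_edges[-1] - eps_x)
    yv = np.clip(y.values, y_edges[0], y_edges[-1] - eps_y)
    n_clipped = int(np.sum((x.values < x_edges[0]) | (x.values >= x_edges[-1]) |
                           (y.values < y_edges[0]) | (y.values >= y_edges[-1])))
    counts, _, _ = np.histogram2d(xv, yv, bins=(x_edges, y_edges))
    return Density2D(x_edges, y_edges, counts.astype(int), n_clipped)


# ---------------------------------------------------------------------------
# frame clustering


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Best-fit (Kabsch) RMSD between every pair of frames of the selection."""
    n = coords.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_fit(coords[i], coords[j]).rmsd
    return mat


def _rmsd_to(coords_i: np.ndarray, coords_j: np.ndarray) -> float:
    return kabsch_fit(coords_i, coords_j).rmsd


@dataclass
class ClusterResult:
    assignments: np.ndarray         # cluster label per frame (0-based)
    representatives: list[int]      # frame index of each cluster's medoid
    sieved_frames: np.ndarray       # frame indices that were clustered directly
    n_clusters: int
    linkage_method: str
    cutoff: float


def cluster_frames(traj: Trajectory, sel: AtomSelector, cutoff: float = 2.0,
                   sieve: int = 5, linkage_method: str = "average") -> ClusterResult:
    """Sieved hierarchical-agglomerative clustering of trajectory frames.

    Every ``sieve``-th frame is clustered by agglomeration (default average
    linkage) on pairwise best-fit RMSD of the selected atoms, merging until
    the minimum inter-cluster distance exceeds ``cutoff``; remaining frames
    join the cluster whose representative (the medoid of its sieved members)
    is nearest by RMSD.  Deterministic given the input order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if sieve < 1:
        raise ValueError("sieve must be ≥ 1")
    atom_idx = [traj.topology.index_of(*a.address)
                for a in select_atoms(traj.topology, sel)]
    if len(atom_idx) < 3:
        raise ValueError("selection must cover at least 3 atoms for best-fit RMSD")
    sub = traj.coords[:, atom_idx, :]
    n = traj.n_frames
    sieved = np.arange(0, n, sieve)

    if sieved.size < 2:
        warnings.warn("fewer than 2 sieved frames; returning a single cluster")
        return ClusterResult(np.zeros(n, dtype=int), [int(sieved[0]) if sieved.size else 0],
                             sieved, 1, linkage_method, cutoff)

    dm = _pairwise_rmsd(sub[sieved])
    Z = linkage(squareform(dm, checks=False), method=linkage_method)
    labels = fcluster(Z, t=cutoff, criterion="distance") - 1

    # Relabel clusters by order of first appearance for determinism.
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    labels = np.array([remap[l] for l in labels])
    n_clusters = len(remap)

    # Medoid representative per cluster (min summed RMSD to cluster members).
    representatives: list[int] = []
    for c in range(n_clusters):
        members = np.where(labels == c)[0]
        sums = dm[np.ix_(members, members)].sum(axis=1)
        representatives.append(int(sieved[members[np.argmin(sums)]]))

    assignments = np.empty(n, dtype=int)
    assignments[sieved] = labels
    rep_coords = [sub[r] for r in representatives]
    sieved_set = set(sieved.tolist())
    for f in range(n):
        if f in sieved_set:
            continue
        d = [_rmsd_to(sub[f], rc) for rc in rep_coords]
        assignments[f] = int(np.argmin(d))
    return ClusterResult(assignments, representatives, sieved, n_clusters,
                         linkage_method, cutoff)


def replica_summary(replicas: list[DescriptorSeries]) -> dict:
    """Pooled (frame-weighted) mean plus per-replica means and the sample SD
    across replica means."""
    if not replicas:
        raise ValueError("no replicas supplied")
    all_values = np.concatenate([r.values for r in replicas])
    per_replica = {r.replica_id: float(np.mean(r.values)) for r in replicas}
    means = np.array(list(per_replica.values()))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return {
        "pooled_mean": float(np.mean(all_values)),
        "per_replica_means": per_replica,
        "sd_across_replicas": sd,
        "n_frames_total": int(all_values.size),
    }


# ---------------------------------------------------------------------------
# sampling-protocol bookkeeping

#: ns per equilibration stage: three 500 ps heating steps (NVT), five 200 ps
#: restraint-release steps (NPT), one unrestrained 500 ps NPT stage.
DEFAULT_EQUILIBRATION_SCHEDULE_NS = (0.5, 0.5, 0.5, 0.2, 0.2, 0.2, 0.2, 0.2, 0.5)


def frames_per_system(production_ns: float = 130.0, skip_ns: float = DEFAULT_SKIP_NS,
                      stride_ps: float = DEFAULT_STRIDE_PS, n_replicas: int = 3) -> int:
    """Frames entering the analysis per system: replicas × analysed span / stride."""
    analysed_ps = (production_ns - skip_ns) * 1000.0
    if analysed_ps <= 0:
        raise ValueError("skip exceeds production length")
    per_replica = int(round(analysed_ps / stride_ps))
    return n_replicas * per_replica


def total_sampling_us(n_systems: int = 4, n_replicas: int = 3,
                      production_ns: float = 130.0) -> float:
    """Aggregate production sampling across all systems, in μs."""
    return n_systems * n_replicas * production_ns / 1000.0


def equilibration_total_ns(schedule_ns=DEFAULT_EQUILIBRATION_SCHEDULE_NS) -> float:
    return float(sum(schedule_ns))
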