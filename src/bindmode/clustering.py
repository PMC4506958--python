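"""Binding-mode clustering of trajectory windows.

The clustering follows the greedy neighbor-count algorithm of Daura et al.:
fitted RMSD is computed between all pairs of frames on a chosen atom set;
for each frame the number of *other* frames with RMSD strictly below a cutoff
is counted; the frame with the most neighbors becomes a cluster center, it
and its neighbors are removed, and the procedure repeats until no frames
remain.  The result is a series of non-overlapping clusters (singletons
allowed) whose sizes are non-increasing.

The default cutoff heuristic takes a fixed fraction (0.70) of the mean
intratrajectory RMSD and snaps it to a 0.1 A grid.  It is a starting point,
not a claim: published analyses search around that value, so every entry
point accepts an explicit cutoff override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .md_analysis import SelectionSpec, pair_stats
from .structure_io import Model, Selection, Trajectory
from .superpose import kabsch_fit

__all__ = [
    "RmsdMatrix",
    "ClusterParams",
    "Cluster",
    "Clustering",
    "CutoffResult",
    "ClusterSummary",
    "ClusterReport",
    "pairwise_rmsd",
    "snap_cutoff",
    "cutoff_from_mean",
    "daura_cluster",
    "cluster_report",
]


@dataclass(frozen=True)
class RmsdMatrix:
    """Symmetric all-pair fitted-RMSD matrix with zero diagonal (Angstrom)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("RMSD matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("RMSD values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        return float(self.values[iu].mean())


@dataclass(frozen=True)
class ClusterParams:
    cutoff: float
    fraction: float = 0.70
    min_report_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Cluster:
    center: int  # 0-based frame position within the window
    members: frozenset


@dataclass(frozen=True)
class Clustering:
    clusters: tuple[Cluster, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignment(self, n: int) -> np.ndarray:
        """Cluster label per frame position (0 = largest cluster)."""
        labels = np.full(n, -1, dtype=int)
        for k, cl in enumerate(self.clusters):
            labels[list(cl.members)] = k
        return labels


def _batch_fitted_rmsd(X: np.ndarray) -> np.ndarray:
    """All-pair fitted RMSD for centered coordinate stacks, shape (n, m, 3).

    Uses the singular values of the 3x3 pair covariance with the reflection
    branch corrected, which equals the Kabsch-fit RMSD without constructing
    rotations.
    """
    n, m, _ = X.shape
    E = np.einsum("imk,imk->i", X, X)
    H = np.einsum("imk,jml->ijkl", X, X)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    sign[sign == 0] = 1.0
    trace = S[..., 0] + S[..., 1] + sign * S[..., 2]
    msd = (E[:, None] + E[None, :] - 2.0 * trace) / m
    vals = np.sqrt(np.clip(msd, 0.0, None))
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    return vals


def pairwise_rmsd(traj_window: Trajectory,
                  sel: Selection | SelectionSpec) -> RmsdMatrix:
    """All-pair fitted RMSD over a window on the selected atoms.

    Entry (i, j) is the RMSD after least-squares superposition of frame j's
    selected atoms onto frame i's.  Requires at least 3 selected atoms.
    """
    selection = sel.superposition_atoms if isinstance(sel, SelectionSpec) else sel
    if len(selection) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    X = traj_window.coords(selection)
    X = X - X.mean(axis=1, keepdims=True)
    return RmsdMatrix(values=_batch_fitted_rmsd(X))


@dataclass(frozen=True)
class CutoffResult:
    """Snapped clustering cutoff plus the exact (unsnapped) value."""

    cutoff: float
    exact: float
    degenerate: bool = False  # all-zero matrix: cutoff carries no information


def snap_cutoff(mean_rmsd: float, fraction: float = 0.70, grid: float = 0.1) -> float:
    """Fraction of a mean RMSD snapped to the nearest grid multiple."""
    exact = fraction * mean_rmsd
    return round(exact / grid) * grid


def cutoff_from_mean(matrix: RmsdMatrix, fraction: float = 0.70,
                     grid: float = 0.1) -> CutoffResult:
    """Default clustering-cutoff heuristic: fraction of the mean pair RMSD.

    The mean is taken over the off-diagonal upper triangle; the cutoff is
    snapped to the nearest multiple of ``grid``.  Requires n >= 2 frames.
    """
    if matrix.n < 2:
        raise ValueError("need at least 2 frames for a mean RMSD")
    mean = matrix.mean_offdiagonal()
    exact = fraction * mean
    snapped = snap_cutoff(mean, fraction, grid)
    return CutoffResult(cutoff=snapped, exact=exact, degenerate=mean == 0.0)


def daura_cluster(matrix: RmsdMatrix, cutoff: float) -> Clustering:
    """Greedy neighbor-count clustering with a strict RMSD cutoff.

    Iteratively, among unassigned frames, each frame's neighbors are the other
    unassigned frames with RMSD strictly less than ``cutoff``; the frame with
    the most neighbors (ties: lowest frame index) becomes a center and forms a
    cluster with its neighbors; all are removed and the process repeats.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.n
    adj = matrix.values < cutoff
    np.fill_diagonal(adj, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        live = adj & unassigned[None, :] & unassigned[:, None]
        counts = np.where(unassigned, live.sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = frozenset({center} | {int(i) for i in np.nonzero(live[center])[0]})
        clusters.append(Cluster(center=center, members=members))
        unassigned[list(members)] = False
    return Clustering(clusters=tuple(clusters))


@dataclass(frozen=True)
class ClusterSummary:
    """Report block for one cluster (frame numbers are 1-based)."""

    size: int
    fraction: float
    center_frame: int
    center_time_ps: float
    mean_intracluster_rmsd: float
    total_contacts: int
    contacts_per_structure: float
    pair_stats: pd.DataFrame
    mean_rmsd_to_crystal: float | None = None
    crystal_to_center_rmsd: float | None = None
    crystal_joins: bool | None = None

    def to_dict(self) -> dict:
        d = {
            "size": self.size,
            "fraction": round(self.fraction, 4),
            "center_frame": self.center_frame,
            "center_time_ps": self.center_time_ps,
            "mean_intracluster_rmsd": round(self.mean_intracluster_rmsd, 3),
            "total_contacts": self.total_contacts,
            "contacts_per_structure": round(self.contacts_per_structure, 2),
            "pair_stats": [
                {**r, "mean_distance": round(r["mean_distance"], 2),
                 "frequency": round(r["frequency"], 1)}
                for r in self.pair_stats.to_dict(orient="records")
            ],
        }
        if self.mean_rmsd_to_crystal is not None:
            d["mean_rmsd_to_crystal"] = round(self.mean_rmsd_to_crystal, 3)
            d["crystal_to_center_rmsd"] = round(self.crystal_to_center_rmsd, 3)
            d["crystal_joins"] = self.crystal_joins
        return d


@dataclass(frozen=True)
class ClusterReport:
    n_frames: int
    cutoff: float
    mean_intratrajectory_rmsd: float
    total_contacts: int
    contacts_per_structure: float
    mean_rmsd_to_crystal: float | None
    clusters: tuple[ClusterSummary, ...]

    def to_dict(self) -> dict:
        d = {
            "n_frames": self.n_frames,
            "cutoff": self.cutoff,
            "mean_intratrajectory_rmsd": round(self.mean_intratrajectory_rmsd, 3),
            "total_contacts": self.total_contacts,
            "contacts_per_structure": round(self.contacts_per_structure, 2),
            "clusters": [c.to_dict() for c in self.clusters],
        }
        if self.mean_rmsd_to_crystal is not None:
            d["mean_rmsd_to_crystal"] = round(self.mean_rmsd_to_crystal, 3)
        return d


def _crystal_selection_coords(crystal: Model, window_model: Model,
                              selection: Selection) -> np.ndarray:
    """Crystal coordinates matched to the window's selected atoms by identity."""
    index = {a.identity: i for i, a in enumerate(crystal.atoms)}
    rows = []
    for i in selection:
        key = window_model.atoms[i].identity
        if key not in index:
            raise ValueError(
                f"crystal reference lacks atom {key}; cannot compare to trajectory")
        rows.append(index[key])
    return crystal.coords()[rows]


def cluster_report(clustering: Clustering, traj_window: Trajectory,
                   sel: SelectionSpec | Selection, matrix: RmsdMatrix,
                   cutoff: float, protein_sel: Selection, ligand_sel: Selection,
                   crystal_ref: Model | None = None,
                   min_report_fraction: float = 0.10,
                   contact_cutoff: float = 3.4,
                   min_frequency: float = 20.0) -> ClusterReport:
    """Per-cluster statistics for clusters above a size threshold.

    For every cluster holding at least ``min_report_fraction`` of the window:
    size, center frame number and time, mean intracluster pair RMSD, total
    contacts and contacts per structure, and the per-pair contact table
    (filtered at ``min_frequency`` percent).  With a crystal reference, also
    the mean RMSD of members to the crystal, the crystal-to-center RMSD, and
    whether the crystal structure would join the cluster (RMSD to the center
    strictly below the clustering cutoff).
    """
    selection = sel.superposition_atoms if isinstance(sel, SelectionSpec) else sel
    n = traj_window.n_frames
    vals = matrix.values
    iu = np.triu_indices(n, k=1)
    mean_intra_all = float(vals[iu].mean()) if n > 1 else 0.0

    crystal_rmsds = None
    if crystal_ref is not None:
        cref = _crystal_selection_coords(crystal_ref, traj_window.frames[0], selection)
        X = traj_window.coords(selection)
        crystal_rmsds = np.array([kabsch_fit(cref, X[i]).rmsd for i in range(n)])

    stats_all = pair_stats(traj_window, protein_sel, ligand_sel,
                           cutoff=contact_cutoff, min_frequency=0.0)
    total_all = int(stats_all["n_frames"].sum())

    summaries = []
    for cl in clustering.clusters:
        if len(cl.members) < min_report_fraction * n:
            continue
        members = sorted(cl.members)
        stats = pair_stats(traj_window, protein_sel, ligand_sel,
                           cutoff=contact_cutoff, min_frequency=min_frequency,
                           frame_subset=np.array(members))
        unfiltered = pair_stats(traj_window, protein_sel, ligand_sel,
                                cutoff=contact_cutoff, min_frequency=0.0,
                                frame_subset=np.array(members))
        total = int(unfiltered["n_frames"].sum())
        sub = vals[np.ix_(members, members)]
        k = len(members)
        intra = float(sub[np.triu_indices(k, k=1)].mean()) if k > 1 else 0.0
        summary = ClusterSummary(
            size=k,
            fraction=k / n,
            center_frame=int(traj_window.frame_ids[cl.center]),
            center_time_ps=float(traj_window.times[cl.center]),
            mean_intracluster_rmsd=intra,
            total_contacts=total,
            contacts_per_structure=total / k,
            pair_stats=stats,
            mean_rmsd_to_crystal=(float(crystal_rmsds[members].mean())
                                  if crystal_rmsds is not None else None),
            crystal_to_center_rmsd=(float(crystal_rmsds[cl.center])
                                    if crystal_rmsds is not None else None),
            crystal_joins=(bool(crystal_rmsds[cl.center] < cutoff)
                           if crystal_rmsds is not None else None),
        )
        summaries.append(summary)

    return ClusterReport(
        n_frames=n,
        cutoff=cutoff,
        mean_intratrajectory_rmsd=mean_intra_all,
        total_contacts=total_all,
        contacts_per_structure=total_all / n,
        mean_rmsd_to_crystal=(float(crystal_rmsds.mean())
                              if crystal_rmsds is not None else None),
        clusters=tuple(summaries),
    )
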