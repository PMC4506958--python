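"""Per-frame contact analysis of MD trajectories.

Given a trajectory (multi-model coordinates with frame times), this module
counts protein-ligand heavy-atom contacts per frame (pairs within a distance
cutoff, 3.4 A by default), extracts analysis windows, derives the atom set
used for all-pair superposition in the clustering step, and tabulates
per-pair contact statistics (occurrence count, frequency, mean distance over
contacting frames).

The superposition-atom selection follows the contact-driven recipe used for
binding-mode clustering: a protein-ligand atom pair qualifies if its shortest
distance anywhere in the window is within the cutoff, and the selection is
the union of atoms of qualifying pairs minus atoms whose names can swap by a
symmetric flip during MD (tyrosine/phenylalanine ring carbons CD1/CD2 and
CE1/CE2; the carboxylate oxygens OAA/OAC of the ligand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Model, Selection, Trajectory

__all__ = [
    "FlipExclusions",
    "SelectionSpec",
    "contact_timeseries",
    "window",
    "derive_superposition_atoms",
    "pair_stats",
]


@dataclass(frozen=True)
class FlipExclusions:
    """Atoms excluded from superposition because MD can flip their naming.

    Defaults: ring carbons CD1/CD2/CE1/CE2 of Tyr and Phe, and the ligand
    carboxylate oxygens OAA/OAC (a 180-degree rotation swaps them).  Arginine
    NH1/NH2 are deliberately not excluded.
    """

    protein: frozenset = frozenset(
        (res, name)
        for res in ("TYR", "PHE")
        for name in ("CD1", "CD2", "CE1", "CE2")
    )
    ligand_names: frozenset = frozenset({"OAA", "OAC"})


@dataclass(frozen=True)
class SelectionSpec:
    """Qualifying contact pairs and the derived superposition atom set."""

    atom_pairs_considered: tuple[tuple[int, int], ...]
    superposition_atoms: Selection
    excluded_flip_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        overlap = set(self.superposition_atoms) & set(self.excluded_flip_atoms)
        if overlap:
            raise ValueError("excluded atoms may not appear in the superposition set")


def _heavy(traj_or_model, sel: Selection) -> list[int]:
    model = traj_or_model.frames[0] if isinstance(traj_or_model, Trajectory) else traj_or_model
    return [i for i in sel if model.atoms[i].element.upper() != "H"]


def _check_selections(traj: Trajectory, protein_sel: Selection, ligand_sel: Selection,
                      include_hydrogens: bool) -> tuple[list[int], list[int]]:
    if len(protein_sel) == 0 or len(ligand_sel) == 0:
        raise ValueError("protein and ligand selections must be non-empty")
    n = traj.frames[0].n_atoms
    for sel in (protein_sel, ligand_sel):
        if sel.atom_indices and sel.atom_indices[-1] >= n:
            raise ValueError("selection index out of range for the trajectory roster")
    if include_hydrogens:
        return list(protein_sel), list(ligand_sel)
    return _heavy(traj, protein_sel), _heavy(traj, ligand_sel)


def contact_timeseries(traj: Trajectory, protein_sel: Selection,
                       ligand_sel: Selection, cutoff: float = 3.4, *,
                       include_hydrogens: bool = False) -> pd.DataFrame:
    """Per-frame protein-ligand contact counts.

    Returns a DataFrame with columns ``frame`` (1-based frame number),
    ``time_ps`` and ``n_contacts`` (heavy-atom pairs within ``cutoff``, each
    pair counted once).
    """
    p_idx, l_idx = _check_selections(traj, protein_sel, ligand_sel, include_hydrogens)
    counts = np.empty(traj.n_frames, dtype=int)
    for f, frame in enumerate(traj.frames):
        coords = frame.coords()
        counts[f] = cKDTree(coords[p_idx]).count_neighbors(
            cKDTree(coords[l_idx]), cutoff)
    return pd.DataFrame({
        "frame": traj.frame_ids,
        "time_ps": traj.times,
        "n_contacts": counts,
    })


def window(traj: Trajectory, first: int, last: int) -> Trajectory:
    """Sub-trajectory of frames ``first``..``last`` (1-based, inclusive).

    Frame positions refer to this trajectory's order; times and original frame
    numbers are preserved, so a window of frames 501-1000 keeps frame numbers
    501..1000 for reporting.
    """
    if not 1 <= first <= last <= traj.n_frames:
        raise ValueError(
            f"window [{first}, {last}] out of range for {traj.n_frames} frames")
    sl = slice(first - 1, last)
    return Trajectory(frames=traj.frames[sl], times=traj.times[sl],
                      frame_ids=traj.frame_ids[sl])


def _candidate_pairs(traj: Trajectory, p_idx: list[int], l_idx: list[int],
                     cutoff: float) -> list[tuple[int, int]]:
    """All (protein, ligand) atom pairs whose distance is <= cutoff in any frame."""
    pairs: set[tuple[int, int]] = set()
    for frame in traj.frames:
        coords = frame.coords()
        tree = cKDTree(coords[p_idx])
        for lk, neigh in enumerate(tree.query_ball_point(coords[l_idx], cutoff)):
            for pk in neigh:
                pairs.add((p_idx[pk], l_idx[lk]))
    return sorted(pairs)


def derive_superposition_atoms(traj_window: Trajectory, protein_sel: Selection,
                               ligand_sel: Selection, cutoff: float = 3.4,
                               flip_exclusions: FlipExclusions | None = None, *,
                               include_hydrogens: bool = False) -> SelectionSpec:
    """Select superposition atoms from contacts observed anywhere in a window.

    A pair qualifies if its minimum distance over the window is <= ``cutoff``;
    the superposition set is the union of atoms in qualifying pairs minus the
    flip-ambiguous atoms.  An empty result is returned as an empty selection
    (the caller decides how to proceed).
    """
    if traj_window.n_frames == 0:
        raise ValueError("window is empty")
    flip = flip_exclusions or FlipExclusions()
    p_idx, l_idx = _check_selections(traj_window, protein_sel, ligand_sel,
                                     include_hydrogens)
    pairs = _candidate_pairs(traj_window, p_idx, l_idx, cutoff)
    model = traj_window.frames[0]
    atom_union = sorted({i for pair in pairs for i in pair})
    lig_set = set(l_idx)
    excluded = []
    kept = []
    for i in atom_union:
        a = model.atoms[i]
        if i in lig_set:
            flip_out = a.name in flip.ligand_names
        else:
            flip_out = (a.resname, a.name) in flip.protein
        (excluded if flip_out else kept).append(i)
    return SelectionSpec(
        atom_pairs_considered=tuple(pairs),
        superposition_atoms=Selection(tuple(kept)),
        excluded_flip_atoms=tuple(excluded),
    )


def pair_stats(traj_window: Trajectory, protein_sel: Selection,
               ligand_sel: Selection, cutoff: float = 3.4,
               min_frequency: float = 20.0, *,
               include_hydrogens: bool = False,
               frame_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-pair contact statistics over a window.

    For each protein-ligand atom pair that is ever in contact, reports the
    number of contacting frames, the appearance frequency in percent of the
    window, and the mean distance over contacting frames.  Rows are sorted by
    count (descending), then mean distance (ascending), then protein atom
    index, and filtered at ``min_frequency`` percent.

    ``frame_subset`` restricts the window to the given 0-based frame positions
    (used for per-cluster statistics); the frequency denominator is then the
    subset size.
    """
    if traj_window.n_frames == 0:
        raise ValueError("window is empty")
    p_idx, l_idx = _check_selections(traj_window, protein_sel, ligand_sel,
                                     include_hydrogens)
    if frame_subset is None:
        frames = list(range(traj_window.n_frames))
    else:
        frames = sorted(int(i) for i in frame_subset)
    sub = Trajectory(frames=[traj_window.frames[i] for i in frames],
                     times=traj_window.times[frames],
                     frame_ids=traj_window.frame_ids[frames])
    pairs = _candidate_pairs(sub, p_idx, l_idx, cutoff)
    n_frames = sub.n_frames
    model = sub.frames[0]
    coords = sub.coords()  # (n_frames, n_atoms, 3)
    rows = []
    for pi, li in pairs:
        d = np.linalg.norm(coords[:, pi, :] - coords[:, li, :], axis=1)
        mask = d <= cutoff
        count = int(mask.sum())
        freq = 100.0 * count / n_frames
        a = model.atoms[pi]
        rows.append({
            "protein_resname": a.resname,
            "protein_resseq": a.resseq,
            "protein_atom": a.name,
            "ligand_atom": model.atoms[li].name,
            "mean_distance": float(d[mask].mean()),
            "n_frames": count,
            "frequency": freq,
            "_protein_index": pi,
        })
    df = pd.DataFrame(rows, columns=[
        "protein_resname", "protein_resseq", "protein_atom", "ligand_atom",
        "mean_distance", "n_frames", "frequency", "_protein_index"])
    df = df.sort_values(["n_frames", "mean_distance", "_protein_index"],
                        ascending=[False, True, True], kind="mergesort")
    df = df[df["frequency"] >= min_frequency]
    return df.drop(columns="_protein_index").reset_index(drop=True)
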