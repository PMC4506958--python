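"""Rigid-body superposition and RMSD.

Least-squares superposition uses the Kabsch algorithm (SVD of the 3x3
covariance matrix with the reflection branch corrected so that the rotation
is proper, det(R) = +1).  On top of the fit, this module provides the
between-model RMSD used for comparing crystal forms and a small "mimicry"
metric: after anchoring two complexes on corresponding protein C-alpha atoms,
the distance between the centroid of a query probe group (e.g. a ligand
carboxylate) and each reference probe group (e.g. glutamate carboxylates of a
bound peptide) quantifies how closely the ligand group occupies the peptide
group's position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Model, Selection

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "DegenerateGeometryError",
    "kabsch_fit",
    "rmsd_after_fit",
    "mimicry_overlap",
    "pair_by_identity",
]

#: RMSD below this is reported as an exact superposition.
ZERO_RMSD_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too degenerate to define a rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


def _check_pointsets(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or mov.ndim != 2 or mov.shape[1] != 3:
        raise ValueError("point sets must have shape (n, 3)")
    if ref.shape[0] != mov.shape[0]:
        raise ValueError(f"point-set sizes differ: {ref.shape[0]} vs {mov.shape[0]}")
    if ref.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")
    return ref, mov


def kabsch_fit(ref_coords: np.ndarray, mov_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares fit of ``mov_coords`` onto ``ref_coords`` (paired by order).

    Returns the proper rigid transform minimizing the RMSD of the moved points
    to the reference, together with that minimal RMSD.  Collinear (or more
    degenerate) configurations raise :class:`DegenerateGeometryError` because
    the optimal rotation is not unique.
    """
    ref, mov = _check_pointsets(ref_coords, mov_coords)
    n = ref.shape[0]
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    A = ref - ref_c
    B = mov - mov_c
    H = B.T @ A  # covariance; rotation maps mov-frame onto ref-frame
    U, S, Vt = np.linalg.svd(H)
    # Degenerate if the two smallest singular values vanish (collinear points)
    scale = max(S[0], 1.0)
    if S[1] / scale < 1e-9:
        raise DegenerateGeometryError("point sets are collinear or degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    moved = B @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    if rmsd < ZERO_RMSD_TOL:
        rmsd = 0.0
    return SuperpositionResult(
        transform=RigidTransform(rotation=R, translation=t), rmsd=rmsd, n_atoms=n)


def rmsd_after_fit(model_a: Model, model_b: Model,
                   sel_a: Selection, sel_b: Selection, *,
                   by_identity: bool = False,
                   exclude_resseq: set[int] | None = None) -> float:
    """Fitted RMSD between two models on paired selections.

    By default atoms are paired by list order (selections must be the same
    length).  With ``by_identity=True`` atoms are matched by (residue number,
    insertion code, atom name), unmatched atoms are dropped pairwise, and
    ``exclude_resseq`` removes listed residues before fitting — the mode used
    when comparing two crystal forms whose models differ in a few residues.
    """
    if by_identity:
        ca, cb = pair_by_identity(model_a, model_b, sel_a, sel_b,
                                  exclude_resseq=exclude_resseq)
        return kabsch_fit(ca, cb).rmsd
    if len(sel_a) != len(sel_b):
        raise ValueError(f"selection sizes differ: {len(sel_a)} vs {len(sel_b)}")
    return kabsch_fit(model_a.coords(sel_a), model_b.coords(sel_b)).rmsd


def pair_by_identity(model_a: Model, model_b: Model,
                     sel_a: Selection, sel_b: Selection,
                     exclude_resseq: set[int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays matched by (residue number, atom name).

    Atoms present in only one model are dropped pairwise, and an explicit
    residue exclusion list can remove e.g. conformationally divergent termini
    before fitting.  Returns two (n, 3) arrays in corresponding order.
    """
    excluded = exclude_resseq or set()

    def keyed(model: Model, sel: Selection) -> dict:
        out = {}
        for i in sel:
            a = model.atoms[i]
            if a.resseq in excluded:
                continue
            out[(a.resseq, a.icode, a.name)] = i
        return out

    ka, kb = keyed(model_a, sel_a), keyed(model_b, sel_b)
    common = sorted(set(ka) & set(kb), key=lambda k: ka[k])
    coords_a = model_a.coords()[[ka[k] for k in common]]
    coords_b = model_b.coords()[[kb[k] for k in common]]
    return coords_a, coords_b


def mimicry_overlap(complex_ref: Model, complex_query: Model,
                    ref_anchor_sel: Selection, query_anchor_sel: Selection,
                    ref_probe_groups: list[Selection],
                    query_probe_group: Selection) -> list[float]:
    """Centroid distances from a superposed query group to reference groups.

    The query complex is superposed onto the reference via the anchor
    selections (corresponding protein C-alpha atoms, paired by order); the
    fitted transform is applied to the query probe group and the distance from
    its centroid to the centroid of each reference probe group is returned, in
    the order of ``ref_probe_groups``.
    """
    if len(query_probe_group) == 0:
        raise ValueError("query probe group is empty")
    if any(len(g) == 0 for g in ref_probe_groups):
        raise ValueError("reference probe group is empty")
    if len(ref_anchor_sel) != len(query_anchor_sel):
        raise ValueError("anchor selections must correspond 1:1")
    fit = kabsch_fit(complex_ref.coords(ref_anchor_sel),
                     complex_query.coords(query_anchor_sel))
    probe = fit.transform.apply(complex_query.coords(query_probe_group)).mean(axis=0)
    out = []
    for group in ref_probe_groups:
        centroid = complex_ref.coords(group).mean(axis=0)
        out.append(float(np.linalg.norm(probe - centroid)))
    return out
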