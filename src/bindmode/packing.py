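"""Crystal-packing contact analysis.

A ligand observed in a crystal structure may be held in place partly by
symmetry-related copies of the protein rather than by the molecule it is
deposited with.  This module expands a model's protein atoms by the
space-group operators plus lattice translations and splits ligand contacts
(heavy-atom pairs within a distance cutoff, 3.4 A by default) into contacts
with the asymmetric-unit molecule and contacts with symmetry mates.

Conventions: only protein atoms (non-het, non-water) are counted on both
sides of the split by default, since the question is how the ligand touches
protein molecules; waters of symmetry mates can be included with a flag.
Fractional coordinates are used only internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Model, Selection, select

__all__ = ["SymmetryMate", "PackingReport", "expand_symmetry", "count_packing_contacts"]


@dataclass(frozen=True)
class SymmetryMate:
    """One symmetry image of the model's protein atoms near a center selection."""

    op_index: int
    lattice_shift: tuple[int, int, int]
    coords: np.ndarray  # transformed protein coordinates, Angstrom

    @property
    def is_identity_image(self) -> bool:
        return self.op_index == 0 and self.lattice_shift == (0, 0, 0)


@dataclass(frozen=True)
class PackingReport:
    """Ligand contact counts split between the asymmetric unit and mates."""

    n_asu_contacts: int
    n_sym_contacts: int
    per_mate: tuple[tuple[int, tuple[int, int, int], int], ...]
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_asu_contacts": self.n_asu_contacts,
            "n_sym_contacts": self.n_sym_contacts,
            "per_mate": [
                {"op_index": op, "lattice_shift": list(shift), "count": n}
                for op, shift, n in self.per_mate
            ],
        }


def _require_crystal(model: Model) -> None:
    if model.cell is None or model.spacegroup is None:
        raise ValueError("model has no unit cell / space group (CRYST1 missing?)")


def _shift_range(center_frac: np.ndarray, image_frac: np.ndarray,
                 margin_frac: np.ndarray) -> list[range]:
    """Per-axis lattice-shift ranges that can bring the image within reach.

    Derived from the fractional extents of the center selection and the
    transformed atoms plus a distance margin, so the search adapts to where
    the molecules sit rather than assuming they lie in the first cell.
    """
    ranges = []
    for k in range(3):
        lo = math.floor(center_frac[:, k].min() - image_frac[:, k].max() - margin_frac[k])
        hi = math.ceil(center_frac[:, k].max() - image_frac[:, k].min() + margin_frac[k])
        ranges.append(range(lo, hi + 1))
    return ranges


def expand_symmetry(model: Model, radius: float, center_sel: Selection,
                    *, include_waters: bool = False) -> list[SymmetryMate]:
    """Symmetry images of the model's protein atoms near a center selection.

    Returns every (operator, lattice shift) image with at least one atom
    within ``radius`` of the center selection's atoms, excluding the identity
    image with zero shift (the asymmetric unit itself).
    """
    _require_crystal(model)
    if len(center_sel) == 0:
        raise ValueError("center selection is empty")
    ortho = model.cell.orthogonalization_matrix
    frac = model.cell.fractionalization_matrix

    mol_idx = [i for i, a in enumerate(model.atoms)
               if not a.is_het and (include_waters or not a.is_water)
               and a.element.upper() != "H"]
    if not mol_idx:
        return []
    coords = model.coords()
    mol_frac = coords[mol_idx] @ frac.T
    center = coords[list(center_sel)]
    center_frac = center @ frac.T
    tree = cKDTree(center)
    # distance margin per fractional axis: radius divided by the cell's
    # perpendicular thickness along that axis (row norms of the frac matrix)
    margin = radius * np.linalg.norm(frac, axis=1)

    mates: list[SymmetryMate] = []
    for op_index, (rot, tran) in enumerate(model.spacegroup.operators):
        image = mol_frac @ rot.T + tran
        rng = _shift_range(center_frac, image, margin)
        for sx in rng[0]:
            for sy in rng[1]:
                for sz in rng[2]:
                    shift = (sx, sy, sz)
                    if op_index == 0 and shift == (0, 0, 0):
                        continue
                    xyz = (image + np.array(shift)) @ ortho.T
                    d, _ = tree.query(xyz, k=1, distance_upper_bound=radius)
                    if np.any(np.isfinite(d)):
                        mates.append(SymmetryMate(op_index=op_index,
                                                  lattice_shift=shift, coords=xyz))
    return mates


def count_packing_contacts(model: Model, ligand_sel: Selection,
                           cutoff: float = 3.4, *,
                           include_mate_waters: bool = False) -> PackingReport:
    """Count ligand contacts to the asymmetric unit versus symmetry mates.

    A contact is a heavy-atom pair at distance <= ``cutoff``; each pair is
    counted once.  The asymmetric-unit count uses the model's own protein
    atoms; the symmetry count sums over all nearby mates with a per-mate
    breakdown.
    """
    _require_crystal(model)
    if len(ligand_sel) == 0:
        raise ValueError("ligand selection is empty")
    coords = model.coords()
    lig_idx = [i for i in ligand_sel if model.atoms[i].element.upper() != "H"]
    lig = coords[lig_idx]
    prot_idx = [i for i, a in enumerate(model.atoms)
                if not a.is_het and not a.is_water and a.element.upper() != "H"]
    lig_tree = cKDTree(lig)

    n_asu = 0
    if prot_idx:
        n_asu = int(lig_tree.count_neighbors(cKDTree(coords[prot_idx]), cutoff))

    per_mate = []
    total = 0
    lig_selection = Selection(tuple(lig_idx))
    for mate in expand_symmetry(model, cutoff, lig_selection,
                                include_waters=include_mate_waters):
        n = int(lig_tree.count_neighbors(cKDTree(mate.coords), cutoff))
        if n:
            per_mate.append((mate.op_index, mate.lattice_shift, n))
            total += n
    per_mate.sort()
    return PackingReport(n_asu_contacts=n_asu, n_sym_contacts=total,
                         per_mate=tuple(per_mate), cutoff=cutoff)
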