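"""Coordinate model and PDB input/output.

Single-model crystal structures (with unit cell and space group from the
CRYST1 record) and multi-model PDB files interpreted as MD trajectories are
read into a small, explicit in-memory model: an ordered list of
:class:`AtomRecord` per :class:`Model`, plus optional crystallographic
metadata.  Parsing is delegated to :mod:`gemmi`; writing is done by an
in-package formatter so that output is deterministic and round-trips.

Coordinates are stored in Angstrom in the orthogonal (Cartesian) frame
throughout the package; fractional coordinates appear only inside the
crystal-packing machinery.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "WATER_RESNAMES",
    "AtomRecord",
    "UnitCell",
    "SpaceGroup",
    "Model",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "RosterMismatchError",
    "SpaceGroupError",
    "SelectionError",
    "space_group",
    "read_pdb",
    "read_multimodel_pdb",
    "write_pdb",
    "write_multimodel_pdb",
    "select",
    "parse_selection",
]

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised when an ATOM/HETATM line cannot be parsed."""


class RosterMismatchError(ValueError):
    """Raised when models of a multi-model file differ in their atom roster."""


class SpaceGroupError(ValueError):
    """Raised for unknown or unsupported space-group symbols."""


class SelectionError(ValueError):
    """Raised for invalid selection expressions."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a PDB model, with residue identity and classification flags."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    bfactor: float
    element: str
    is_het: bool
    is_water: bool

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.resname, self.resseq)

    @property
    def identity(self) -> tuple[str, int, str, str, str]:
        """Roster identity: (chain, resseq, icode, resname, name)."""
        return (self.chain, self.resseq, self.icode, self.resname, self.name)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180)")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with xyz = M @ fractional (PDB convention: a along x)."""
        ca, cb, cg = (math.cos(math.radians(t)) for t in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)


# -- space groups -----------------------------------------------------------

# Symmetry operators are represented as (R, t) acting on fractional
# coordinates: f' = R @ f + t.  Internally translations are integers over a
# denominator of 24, which represents halves, thirds, quarters and sixths
# exactly; full operator sets are generated from tabulated generators by
# closure under composition modulo lattice translations.

_DEN = 24

_GENERATORS: dict[str, tuple[str, ...]] = {
    "P 1": (),
    "P 21 21 21": ("-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z"),
    "P 65 2 2": ("x-y,x,z+5/6", "y,x,-z+2/3"),
}

_SYMBOL_ALIASES = {
    "P1": "P 1",
    "P212121": "P 21 21 21",
    "P6522": "P 65 2 2",
    "P6522(179)": "P 65 2 2",
}

_TERM_RE = re.compile(r"([+-]?)(\d+/\d+|\d+|[xyz])")


def _parse_triplet(triplet: str) -> tuple[tuple, tuple]:
    rot = np.zeros((3, 3), dtype=int)
    tran = np.zeros(3, dtype=int)
    parts = triplet.replace(" ", "").lower().split(",")
    if len(parts) != 3:
        raise SpaceGroupError(f"bad symmetry triplet: {triplet!r}")
    for i, part in enumerate(parts):
        consumed = 0
        for sign, tok in _TERM_RE.findall(part):
            s = -1 if sign == "-" else 1
            if tok in "xyz":
                rot[i, "xyz".index(tok)] += s
            elif "/" in tok:
                num, den = (int(v) for v in tok.split("/"))
                if (_DEN * num) % den:
                    raise SpaceGroupError(f"translation {tok} not representable")
                tran[i] += s * (_DEN * num) // den
            else:
                tran[i] += s * _DEN * int(tok)
            consumed += len(sign) + len(tok)
        if consumed != len(part):
            raise SpaceGroupError(f"bad symmetry triplet: {triplet!r}")
    return tuple(map(tuple, rot)), tuple(tran % _DEN)


def _compose(op1: tuple, op2: tuple) -> tuple:
    r1, t1 = np.array(op1[0]), np.array(op1[1])
    r2, t2 = np.array(op2[0]), np.array(op2[1])
    rot = r1 @ r2
    tran = (r1 @ t2 + t1) % _DEN
    return tuple(map(tuple, rot)), tuple(int(v) for v in tran)


_IDENTITY_OP = (((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))


def _closure(generators: Iterable[tuple]) -> list[tuple]:
    ops = {_IDENTITY_OP}
    frontier = list(generators)
    ops.update(frontier)
    while frontier:
        new = []
        for a in list(ops):
            for b in list(ops):
                c = _compose(a, b)
                if c not in ops:
                    ops.add(c)
                    new.append(c)
        frontier = new
        if len(ops) > 192:
            raise SpaceGroupError("operator closure did not terminate")
    return sorted(ops, key=lambda op: (op != _IDENTITY_OP, op))


@dataclass(frozen=True)
class SpaceGroup:
    """A space group as its Hermann-Mauguin symbol plus explicit operators.

    ``operators`` is an ordered list of ``(rotation, translation)`` pairs over
    fractional coordinates; the identity comes first.
    """

    hm_symbol: str
    _ops: tuple = field(repr=False)

    @property
    def operators(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (np.array(rot, dtype=int), np.array(tran, dtype=float) / _DEN)
            for rot, tran in self._ops
        ]

    def __len__(self) -> int:
        return len(self._ops)


def _normalize_symbol(symbol: str) -> str:
    compact = symbol.replace(" ", "").replace("_", "").upper()
    if compact in _SYMBOL_ALIASES:
        return _SYMBOL_ALIASES[compact]
    for hm in _GENERATORS:
        if hm.replace(" ", "") == compact:
            return hm
    return symbol.strip()


def space_group(symbol: str) -> SpaceGroup:
    """Build a :class:`SpaceGroup` from its Hermann-Mauguin symbol.

    The symbols needed for the structures this package targets (P1,
    P2\\ :sub:`1`\\ 2\\ :sub:`1`\\ 2\\ :sub:`1`, P6\\ :sub:`5`\\ 22) are generated
    in-package from tabulated generators; any other symbol is delegated to
    gemmi's space-group tables.
    """
    hm = _normalize_symbol(symbol)
    if hm in _GENERATORS:
        gens = [_parse_triplet(t) for t in _GENERATORS[hm]]
        return SpaceGroup(hm_symbol=hm, _ops=tuple(_closure(gens)))
    found = gemmi.find_spacegroup_by_name(symbol)
    if found is None:
        raise SpaceGroupError(
            f"unknown space-group symbol {symbol!r}; built-in symbols: "
            + ", ".join(sorted(_GENERATORS))
        )
    ops = [
        (tuple(tuple(r // gemmi.Op.DEN for r in row) for row in op.rot),
         tuple((t * _DEN) // gemmi.Op.DEN for t in op.tran))
        for op in found.operations()
    ]
    return SpaceGroup(hm_symbol=found.hm, _ops=tuple(ops))


@dataclass
class Model:
    """An ordered set of atoms plus optional crystallographic metadata."""

    atoms: list[AtomRecord]
    cell: UnitCell | None = None
    spacegroup: SpaceGroup | None = None
    model_id: int = 1

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self, selection: "Selection | None" = None) -> np.ndarray:
        xyz = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)
        xyz = xyz.reshape(-1, 3)
        if selection is None:
            return xyz
        return xyz[list(selection.atom_indices)]

    def with_coords(self, xyz: np.ndarray) -> "Model":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Model(atoms=atoms, cell=self.cell, spacegroup=self.spacegroup,
                     model_id=self.model_id)

    def roster(self) -> tuple:
        return tuple(a.identity for a in self.atoms)


@dataclass
class Trajectory:
    """Ordered frames with times in ps; all frames share one atom roster."""

    frames: list[Model]
    times: np.ndarray
    frame_ids: np.ndarray = None  # 1-based frame numbers, preserved by windowing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_ids is None:
            self.frame_ids = np.arange(1, len(self.frames) + 1)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, selection: "Selection | None" = None) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_selected, 3)."""
        return np.stack([f.coords(selection) for f in self.frames])


@dataclass(frozen=True)
class Selection:
    """Ordered atom indices into ``Model.atoms``; strictly increasing, unique."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.atom_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SelectionError("selection indices must be strictly increasing")
        if any(i < 0 for i in idx):
            raise SelectionError("selection indices must be non-negative")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def __iter__(self):
        return iter(self.atom_indices)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return Path(source).read_text()
    if isinstance(source, str):
        return source
    if isinstance(source, bytes):
        return source.decode()
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    raise TypeError(f"cannot read PDB from {type(source).__name__}")


def _prevalidate(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed coordinate record") from exc


_ELEMENT_FROM_NAME = re.compile(r"[A-Za-z]")


def _infer_element(name: str) -> str:
    # PDB name columns 13-14 carry the element; for 4-char names (and typical
    # heavy-atom names) the first alphabetic character is the symbol.
    stripped = name.strip()
    m = _ELEMENT_FROM_NAME.search(stripped)
    return m.group(0).upper() if m else "X"


def _convert_model(gmodel: gemmi.Model, altloc_keep: str,
                   water_resnames: frozenset, model_id: int) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    for chain in gmodel:
        for residue in chain:
            is_het = residue.het_flag == "H"
            is_water = residue.name in water_resnames
            for atom in residue:
                alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                if alt not in ("", altloc_keep):
                    continue
                element = atom.element.name
                if not element or element == "X":
                    element = _infer_element(atom.name)
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    altloc=alt,
                    resname=residue.name,
                    chain=chain.name,
                    resseq=residue.seqid.num,
                    icode=residue.seqid.icode.strip(),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    occupancy=atom.occ,
                    bfactor=atom.b_iso,
                    element=element.upper(),
                    is_het=is_het,
                    is_water=is_water,
                ))
    return atoms


def _parse_structure(text: str) -> gemmi.Structure:
    _prevalidate(text)
    st = gemmi.read_pdb_string(text)
    return st


def _cell_and_group(st: gemmi.Structure) -> tuple[UnitCell | None, SpaceGroup | None]:
    cell = None
    if st.cell.is_crystal():
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = None
    if st.spacegroup_hm:
        sg = space_group(st.spacegroup_hm)
    return cell, sg


def read_pdb(source, *, altloc: str = "A",
             water_resnames: frozenset = WATER_RESNAMES) -> Model:
    """Read a single-model PDB file (path, text, bytes, or stream).

    HETATM records are flagged ``is_het``; waters are recognized by residue
    name.  Alternate locations other than blank or ``altloc`` are dropped.
    Raises :class:`PDBParseError` for malformed coordinate records and
    :class:`SpaceGroupError` for unknown CRYST1 space-group symbols.
    """
    st = _parse_structure(_read_text(source))
    if len(st) > 1:
        raise PDBParseError(
            f"expected a single-model file, found {len(st)} MODEL blocks; "
            "use read_multimodel_pdb for trajectories")
    cell, sg = _cell_and_group(st)
    atoms = _convert_model(st[0], altloc, water_resnames, 1) if len(st) else []
    return Model(atoms=atoms, cell=cell, spacegroup=sg, model_id=1)


def read_multimodel_pdb(source, start_time: float = 20.0, stride: float = 20.0, *,
                        altloc: str = "A",
                        water_resnames: frozenset = WATER_RESNAMES) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Frame times are ``start_time + i * stride`` in ps (frame 0 at
    ``start_time``), matching a trajectory recorded at a fixed interval.
    All models must share the same atom roster (chain, residue, atom names in
    order); a mismatch raises :class:`RosterMismatchError` naming the first
    offending model.
    """
    st = _parse_structure(_read_text(source))
    if len(st) == 0:
        raise PDBParseError("no models found")
    cell, sg = _cell_and_group(st)
    frames = []
    for i, gmodel in enumerate(st):
        atoms = _convert_model(gmodel, altloc, water_resnames, i + 1)
        frames.append(Model(atoms=atoms, cell=cell, spacegroup=sg, model_id=i + 1))
    ref = frames[0].roster()
    for i, frame in enumerate(frames[1:], start=2):
        if frame.roster() != ref:
            raise RosterMismatchError(
                f"model {i} differs from model 1 in its atom roster "
                f"({frame.n_atoms} vs {frames[0].n_atoms} atoms)")
    times = start_time + stride * np.arange(len(frames))
    return Trajectory(frames=frames, times=times)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.is_het else "ATOM  "
    return (
        f"{record}{serial % 100000:5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' '}{atom.resname:>3s} {atom.chain[:1] or 'A'}"
        f"{atom.resseq % 10000:4d}{atom.icode or ' '}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
        f"{atom.element:>2s}"
    )


def _cryst1_line(cell: UnitCell, sg: SpaceGroup | None) -> str:
    symbol = sg.hm_symbol if sg is not None else "P 1"
    return (
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {symbol:<11s}"
    )


def _model_lines(model: Model) -> list[str]:
    return [_atom_line(a, i + 1) for i, a in enumerate(model.atoms)]


def write_pdb(model: Model, path=None) -> str:
    """Write a model as PDB text; returns the text, optionally writing a file."""
    lines = []
    if model.cell is not None:
        lines.append(_cryst1_line(model.cell, model.spacegroup))
    lines.extend(_model_lines(model))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_multimodel_pdb(traj: Trajectory, path=None) -> str:
    """Write a trajectory as a multi-model PDB file."""
    lines = []
    first = traj.frames[0]
    if first.cell is not None:
        lines.append(_cryst1_line(first.cell, first.spacegroup))
    for i, frame in enumerate(traj.frames):
        lines.append(f"MODEL {i + 1:8d}")
        lines.extend(_model_lines(frame))
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def select(model: Model, *,
           chain: str | None = None,
           resseq_range: tuple[int, int] | None = None,
           names: Iterable[str] | None = None,
           resnames: Iterable[str] | None = None,
           het: bool | None = None,
           water: bool | None = None,
           elements: Iterable[str] | None = None,
           exclude_resseq: Iterable[int] | None = None,
           heavy_only: bool = False) -> Selection:
    """Select atoms by combining criteria; returns an ordered :class:`Selection`.

    All criteria are conjunctive; ``None`` means "no constraint".  An empty
    result is a valid (empty) selection.
    """
    names = {n.strip().upper() for n in names} if names is not None else None
    resnames = {r.strip().upper() for r in resnames} if resnames is not None else None
    elements = {e.strip().upper() for e in elements} if elements is not None else None
    excluded = set(exclude_resseq) if exclude_resseq is not None else None
    idx = []
    for i, a in enumerate(model.atoms):
        if chain is not None and a.chain != chain:
            continue
        if resseq_range is not None and not resseq_range[0] <= a.resseq <= resseq_range[1]:
            continue
        if names is not None and a.name.upper() not in names:
            continue
        if resnames is not None and a.resname.upper() not in resnames:
            continue
        if het is not None and a.is_het != het:
            continue
        if water is not None and a.is_water != water:
            continue
        if elements is not None and a.element.upper() not in elements:
            continue
        if excluded is not None and a.resseq in excluded:
            continue
        if heavy_only and a.element.upper() == "H":
            continue
        idx.append(i)
    return Selection(atom_indices=tuple(idx))


_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_selection(model: Model, expr: str) -> Selection:
    """Parse a compact selection expression into a :class:`Selection`.

    Supported forms: ``ca`` / ``ca:325-609`` (protein C-alpha atoms, optional
    residue range), ``protein``, ``ligand`` (het, non-water), ``water``,
    ``name:OAA,OAC``, ``resname:LG1``, ``resseq:325-609``.
    """
    expr = expr.strip()
    head, _, arg = expr.partition(":")
    head = head.lower()
    if head == "ca":
        rng = None
        if arg:
            m = _RANGE_RE.match(arg)
            if not m:
                raise SelectionError(f"bad residue range {arg!r}")
            rng = (int(m.group(1)), int(m.group(2)))
        return select(model, names={"CA"}, het=False, water=False, resseq_range=rng)
    if head == "protein":
        return select(model, het=False, water=False)
    if head == "ligand":
        if arg:
            return select(model, het=True, water=False, resnames={arg})
        return select(model, het=True, water=False)
    if head == "water":
        return select(model, water=True)
    if head == "name":
        if not arg:
            raise SelectionError("name: requires a comma-separated atom-name list")
        return select(model, names=set(arg.split(",")))
    if head == "resname":
        if not arg:
            raise SelectionError("resname: requires a residue name")
        return select(model, resnames={arg})
    if head == "resseq":
        m = _RANGE_RE.match(arg)
        if not m:
            raise SelectionError(f"bad residue range {arg!r}")
        return select(model, resseq_range=(int(m.group(1)), int(m.group(2))))
    raise SelectionError(f"unrecognized selection expression {expr!r}")
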