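"""Synthetic fixtures for the whole analysis pipeline.

Three deterministic generators provide everything the pipeline needs without
external data:

* :func:`simulate_trajectory` - a rigid pseudo-receptor plus a ligand whose
  pose per frame is drawn from a set of planted binding modes (rigid
  transform + isotropic Gaussian noise, stated occupancies), with optional
  dissociated frames placed far from the receptor.  Ground-truth frame
  labels are returned alongside the trajectory.
* :func:`make_crystal_fixture` - a toy crystal (unit cell + space group)
  built so the ligand bridges the asymmetric molecule and a chosen symmetry
  mate with an exact, known number of packing contacts.
* :func:`make_interaction_fixture` - a synthetic protein fragment + ligand +
  waters realizing exactly a requested number of hydrogen bonds, nonpolar
  contacts, electrostatic contacts and water bridges under default rules.

Occupancies are realized exactly (largest-remainder apportionment of frames,
then a seeded shuffle) rather than by i.i.d. draws, so that planted cluster
sizes are known to within rounding; frame-to-frame kinetics is deliberately
not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .interactions import InteractionRules, build_interaction_table
from .structure_io import (AtomRecord, Model, Selection, SpaceGroup, Trajectory,
                           UnitCell, select, space_group)
from .superpose import RigidTransform

__all__ = [
    "ModeSpec",
    "TrajectorySimSpec",
    "CrystalSimSpec",
    "InfeasiblePlacementError",
    "make_receptor_template",
    "make_ligand_template",
    "binding_mode_specs",
    "simulate_trajectory",
    "make_crystal_fixture",
    "make_interaction_fixture",
]


class InfeasiblePlacementError(ValueError):
    """Raised when a requested crystal fixture cannot be realized."""


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

_SIDECHAINS = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "SER": ("CB", "OG"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "GLY": (),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
}
_RES_CYCLE = ("ALA", "ARG", "TYR", "SER", "ASN", "PHE", "GLY", "LYS")


def _atom(serial, name, resname, resseq, xyz, element, *, chain="A",
          is_het=False, is_water=False) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, altloc="", resname=resname,
                      chain=chain, resseq=resseq, icode="",
                      x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                      occupancy=1.0, bfactor=0.0, element=element,
                      is_het=is_het, is_water=is_water)


def make_receptor_template(n_res: int = 24, start_resseq: int = 325) -> Model:
    """Deterministic pseudo-protein: a helical backbone trace with named
    side-chain pseudo-atoms, including Tyr/Phe ring carbons so flip-exclusion
    logic is exercised without real structures."""
    atoms: list[AtomRecord] = []
    serial = 1
    radius, rise, turn = 2.3, 1.5, math.radians(100.0)
    for i in range(n_res):
        resname = _RES_CYCLE[i % len(_RES_CYCLE)]
        resseq = start_resseq + i
        phi = i * turn
        axis_point = np.array([0.0, 0.0, i * rise])
        out = np.array([math.cos(phi), math.sin(phi), 0.0])
        perp = np.array([-math.sin(phi), math.cos(phi), 0.0])
        ca = axis_point + radius * out
        backbone = {
            "N": ca - 0.8 * perp + np.array([0, 0, -0.6]),
            "CA": ca,
            "C": ca + 0.9 * perp + np.array([0, 0, 0.5]),
            "O": ca + 1.1 * perp + np.array([0, 0, 1.6]),
        }
        for name, pos in backbone.items():
            atoms.append(_atom(serial, name, resname, resseq, pos, name[0]))
            serial += 1
        for j, name in enumerate(_SIDECHAINS[resname]):
            # stretch the side chain radially outward, with a small lateral
            # zigzag so branch atoms (NH1/NH2, ring carbons) do not coincide
            lateral = 0.7 * ((-1) ** j) * perp
            pos = ca + (1.4 + 1.1 * j) * out + lateral * (j % 3) / 2.0
            atoms.append(_atom(serial, name, resname, resseq, pos, name[0]))
            serial += 1
    return Model(atoms=atoms)


_LIGAND_HEAVY = (
    # name, element -- carboxylate end first so it faces the receptor
    ("OAA", "O"), ("CAT", "C"), ("OAC", "O"), ("CAS", "C"), ("OAO", "O"),
    ("CAD", "C"), ("CAE", "C"), ("CAF", "C"), ("CAG", "C"), ("CAH", "C"),
    ("CAI", "C"), ("NAM", "N"), ("CAJ", "C"), ("OAB", "O"), ("NAN", "N"),
    ("CAK", "C"), ("NAO", "N"), ("NAP", "N"), ("OAQ", "O"), ("CAL", "C"),
    ("CAU", "C"), ("CAV", "C"), ("CAW", "C"), ("CAX", "C"), ("OAR", "O"),
    ("CAZ", "C"),
)


def make_ligand_template(resname: str = "LIG", resseq: int = 701,
                         with_hydrogens: bool = True) -> Model:
    """Deterministic ~39-atom ligand (26 heavy + 13 H) with the atom names the
    contact analysis cares about (OAA/OAC carboxylate, OAB ureido oxygen,
    CAT carboxylate carbon, NAM/NAN/NAP nitrogens, ...).

    The geometry is a compact curved chain; it is a geometric stand-in for
    pose bookkeeping, not a chemically valid conformer.
    """
    atoms = []
    serial = 1
    for i, (name, element) in enumerate(_LIGAND_HEAVY):
        pos = np.array([1.25 * i,
                        1.4 * math.sin(i * 1.05),
                        0.9 * math.cos(i * 0.65)])
        atoms.append(_atom(serial, name, resname, resseq, pos, element,
                           chain="L", is_het=True))
        serial += 1
    if with_hydrogens:
        for k in range(13):
            heavy = atoms[2 * k]
            pos = heavy.xyz + np.array([0.0, 0.0, 1.0])
            atoms.append(_atom(serial, f"HA{chr(65 + k)}", resname, resseq, pos,
                               "H", chain="L", is_het=True))
            serial += 1
    return Model(atoms=atoms)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeSpec:
    """One planted binding mode: a ligand pose and its occupancy."""

    pose: RigidTransform
    weight: float
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("mode weight must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass
class TrajectorySimSpec:
    """Specification of a planted-mode trajectory simulation."""

    receptor_template: Model
    ligand_template: Model
    modes: list[ModeSpec]
    n_frames: int = 500
    seed: int = 0
    start_time: float = 20.0
    stride: float = 20.0
    sigma_receptor: float = 0.0
    dissociation_displacement: float = 50.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        total = sum(m.weight for m in self.modes)
        if total > 1.0 + 1e-9:
            raise ValueError(f"mode weights sum to {total:.3f} > 1")
        if self.dissociation_displacement < 20.0:
            raise ValueError("dissociation displacement must be >= 20 A")


def _apportion(weights: list[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n frames to weights (may sum < 1;
    the remainder is the dissociated count)."""
    raw = [w * n for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    leftover = n - sum(counts) - int(round((1.0 - sum(weights)) * n))
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(max(0, leftover)):
        counts[order[i % len(order)]] += 1
    return counts


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def binding_mode_specs(receptor: Model, ligand: Model,
                       weights: tuple[float, ...] = (0.6, 0.25, 0.15),
                       noise_sigma: float = 0.1,
                       approach_distance: float = 3.1,
                       anchor_stride: int = 7) -> list[ModeSpec]:
    """Construct well-separated binding modes docked onto a receptor.

    Mode ``m`` anchors the ligand's first atom (the carboxylate oxygen of the
    default template) ``approach_distance`` Angstrom outside the C-alpha atom
    of every ``anchor_stride``-th residue, with a distinct rigid rotation, so
    bound frames are guaranteed protein-ligand contacts and modes are many
    Angstrom apart.
    """
    ca = select(receptor, names={"CA"})
    ca_coords = receptor.coords(ca)
    centroid = receptor.coords().mean(axis=0)
    lig_coords = ligand.coords()
    specs = []
    for m, w in enumerate(weights):
        idx = (2 + m * anchor_stride) % len(ca_coords)
        anchor = ca_coords[idx]
        out = anchor - centroid
        out[2] = 0.0
        out /= np.linalg.norm(out)
        target = anchor + approach_distance * out
        R = _rotation_about_z(40.0 * m + 15.0)
        t = target - R @ lig_coords[0]
        specs.append(ModeSpec(pose=RigidTransform(rotation=R, translation=t),
                              weight=w, noise_sigma=noise_sigma))
    return specs


def simulate_trajectory(spec: TrajectorySimSpec) -> tuple[Trajectory, np.ndarray]:
    """Simulate a planted-mode trajectory; returns (trajectory, labels).

    Per frame, the ligand pose is one of the planted modes (or dissociated,
    label -1) with per-atom isotropic Gaussian noise; the receptor is the
    rigid template, optionally jittered.  Occupancies are realized exactly
    via apportionment and a seeded shuffle, and the whole simulation is
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    counts = _apportion([m.weight for m in spec.modes], n)
    labels = np.concatenate(
        [np.full(c, i, dtype=int) for i, c in enumerate(counts)]
        + [np.full(n - sum(counts), -1, dtype=int)])
    rng.shuffle(labels)

    rec = spec.receptor_template
    lig = spec.ligand_template
    rec_xyz = rec.coords()
    lig_xyz = lig.coords()
    centroid = rec_xyz.mean(axis=0)
    away = np.array([1.0, 0.0, 0.0])
    base_noise = spec.modes[0].noise_sigma if spec.modes else 0.1

    roster = list(rec.atoms) + list(lig.atoms)
    n_rec = len(rec.atoms)
    template = Model(atoms=roster)
    frames = []
    for f in range(n):
        r = rec_xyz + (rng.normal(0.0, spec.sigma_receptor, rec_xyz.shape)
                       if spec.sigma_receptor > 0 else 0.0)
        lab = labels[f]
        if lab >= 0:
            mode = spec.modes[lab]
            pose = mode.pose.apply(lig_xyz)
            pose = pose + rng.normal(0.0, mode.noise_sigma, lig_xyz.shape)
        else:
            pose = (lig_xyz + centroid + spec.dissociation_displacement * away
                    + rng.normal(0.0, base_noise, lig_xyz.shape))
        coords = np.vstack([r, pose])
        frames.append(template.with_coords(coords))
    times = spec.start_time + spec.stride * np.arange(n)
    traj = Trajectory(frames=frames, times=times)
    return traj, labels


# ---------------------------------------------------------------------------
# toy crystals
# ---------------------------------------------------------------------------


@dataclass
class CrystalSimSpec:
    """Toy crystal: a ligand bridging the asymmetric molecule and one mate."""

    cell: UnitCell
    spacegroup: SpaceGroup | str
    n_sym_contacts: int = 3
    n_asu_contacts: int = 0
    contact_distance: float = 3.0
    mate_op: int = 1
    mate_shift: tuple[int, int, int] = (0, 0, 0)
    cutoff: float = 3.4

    def __post_init__(self) -> None:
        if isinstance(self.spacegroup, str):
            self.spacegroup = space_group(self.spacegroup)
        if self.n_sym_contacts < 0 or self.n_asu_contacts < 0:
            raise ValueError("contact counts must be non-negative")
        if not self.contact_distance <= self.cutoff:
            raise ValueError("contact distance must not exceed the cutoff")
        if self.n_sym_contacts and self.mate_op == 0 and tuple(self.mate_shift) == (0, 0, 0):
            raise InfeasiblePlacementError(
                "the identity image with zero shift is the asymmetric unit itself")
        if self.mate_op >= len(self.spacegroup):
            raise ValueError(f"mate_op {self.mate_op} out of range "
                             f"for {self.spacegroup.hm_symbol}")


def _brute_force_counts(model: Model, cutoff: float, max_shift: int = 2
                        ) -> tuple[int, int]:
    """Exhaustive packing-contact counts over all ops x shifts in +-max_shift."""
    frac = model.cell.fractionalization_matrix
    ortho = model.cell.orthogonalization_matrix
    coords = model.coords()
    prot = np.array([coords[i] for i, a in enumerate(model.atoms)
                     if not a.is_het and not a.is_water])
    lig = np.array([coords[i] for i, a in enumerate(model.atoms)
                    if a.is_het and not a.is_water and a.element.upper() != "H"])
    prot_frac = prot @ frac.T
    n_asu = n_sym = 0
    rng = range(-max_shift, max_shift + 1)
    for op_index, (rot, tran) in enumerate(model.spacegroup.operators):
        base = prot_frac @ rot.T + tran
        for sx in rng:
            for sy in rng:
                for sz in rng:
                    xyz = (base + np.array([sx, sy, sz])) @ ortho.T
                    d = np.linalg.norm(lig[:, None, :] - xyz[None, :, :], axis=2)
                    count = int((d <= cutoff).sum())
                    if op_index == 0 and (sx, sy, sz) == (0, 0, 0):
                        n_asu += count
                    else:
                        n_sym += count
    return n_asu, n_sym


def make_crystal_fixture(spec: CrystalSimSpec) -> Model:
    """Build a single-ASU model realizing exact packing-contact counts.

    Protein pseudo-atoms are spaced widely (8 A) so each requested contact is
    a single, isolated pair; ligand atoms are placed ``contact_distance`` from
    chosen mate-image (and optionally asymmetric-unit) atoms.  The returned
    placement is verified by exhaustive enumeration; an unrealizable request
    raises :class:`InfeasiblePlacementError`.
    """
    sg: SpaceGroup = spec.spacegroup
    ortho = spec.cell.orthogonalization_matrix
    frac = np.linalg.inv(ortho)
    rot, tran = sg.operators[spec.mate_op]
    shift = np.array(spec.mate_shift, dtype=float)

    n_prot = spec.n_sym_contacts + spec.n_asu_contacts + 2
    base = ortho @ np.array([0.2, 0.2, 0.2])
    # compact 3-D grid, 8 A spacing: wide enough to isolate each contact pair,
    # small enough to stay clear of neighboring images in modest cells
    side = math.ceil(n_prot ** (1.0 / 3.0))
    prot_xyz = np.array([
        base + 8.0 * np.array([i % side, (i // side) % side, i // side ** 2])
        for i in range(n_prot)])

    lig_xyz = []
    for i in range(spec.n_sym_contacts):
        f = frac @ prot_xyz[i]
        image = ortho @ (rot @ f + tran + shift)
        lig_xyz.append(image + np.array([0.0, spec.contact_distance, 0.0]))
    for j in range(spec.n_asu_contacts):
        anchor = prot_xyz[spec.n_sym_contacts + j]
        lig_xyz.append(anchor + np.array([0.0, spec.contact_distance, 0.0]))
    if not lig_xyz:
        lig_xyz.append(base + np.array([0.0, 15.0, 0.0]))
    lig_xyz = np.array(lig_xyz)

    atoms = []
    serial = 1
    for i, pos in enumerate(prot_xyz):
        atoms.append(_atom(serial, "CA", "GLY", 10 + i, pos, "C"))
        serial += 1
    for j, pos in enumerate(lig_xyz):
        atoms.append(_atom(serial, f"C{j + 1}", "LIG", 701, pos, "C",
                           chain="L", is_het=True))
        serial += 1
    model = Model(atoms=atoms, cell=spec.cell, spacegroup=sg)

    n_asu, n_sym = _brute_force_counts(model, spec.cutoff)
    if (n_asu, n_sym) != (spec.n_asu_contacts, spec.n_sym_contacts):
        raise InfeasiblePlacementError(
            f"placement realizes (asu={n_asu}, sym={n_sym}) instead of the "
            f"requested (asu={spec.n_asu_contacts}, sym={spec.n_sym_contacts}); "
            "use a larger cell or fewer contacts")
    return model


# ---------------------------------------------------------------------------
# interaction-geometry fixtures
# ---------------------------------------------------------------------------


def _directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (k + 0.5) / n
    r = np.sqrt(1 - z ** 2)
    theta = 2 * np.pi * k / golden
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def make_interaction_fixture(n_hb: int = 1, n_np: int = 1, n_es: int = 1,
                             n_bridges: int = 1) -> Model:
    """Synthetic complex realizing exact interaction counts under default rules.

    Four spatially isolated sites (>= 25 A apart) carry the requested
    interactions: serine OG donors at hydrogen-bond distance from the ligand
    ureido oxygen OAB; alanine CB carbons at nonpolar distance from the
    carboxylate carbon CAT; arginine NH1 guanidinium atoms in the
    electrostatic shell (3.7 A) around the carboxylate oxygen OAA; and
    asparagine-water-ligand chains bridging to the ring oxygen OAR.
    """
    for v in (n_hb, n_np, n_es, n_bridges):
        if v < 0:
            raise ValueError("requested counts must be non-negative")
    atoms: list[AtomRecord] = []
    serial = [0]

    def add(name, resname, resseq, xyz, element, **kw):
        serial[0] += 1
        atoms.append(_atom(serial[0], name, resname, resseq, xyz, element, **kw))

    lig_sites = {"OAB": np.array([0.0, 0.0, 0.0]),
                 "CAT": np.array([30.0, 0.0, 0.0]),
                 "OAA": np.array([60.0, 0.0, 0.0]),
                 "OAR": np.array([90.0, 0.0, 0.0])}

    # hydrogen bonds: Ser OG (donor) at 2.8 A from the OAB acceptor, CB
    # antecedent radially outward so the donor angle is 180 degrees
    for k, d in enumerate(_directions(max(n_hb, 1))[:n_hb]):
        og = lig_sites["OAB"] + 2.8 * d
        add("OG", "SER", 10 + k, og, "O")
        add("CB", "SER", 10 + k, lig_sites["OAB"] + 4.2 * d, "C")
    # nonpolar: Ala CB at 3.2 A from the CAT carbon
    for k, d in enumerate(_directions(max(n_np, 1))[:n_np]):
        add("CB", "ALA", 40 + k, lig_sites["CAT"] + 3.2 * d, "C")
    # electrostatic: Arg NH1 at 3.7 A from the charged OAA (beyond hb_max)
    for k, d in enumerate(_directions(max(n_es, 1))[:n_es]):
        add("NH1", "ARG", 70 + k, lig_sites["OAA"] + 3.7 * d, "N")
        add("CZ", "ARG", 70 + k, lig_sites["OAA"] + 5.0 * d, "C")
    # water bridges: Asn OD1 -- 2.7 -- water O -- 2.7 -- OAR, collinear
    for k, d in enumerate(_directions(max(n_bridges, 1))[:n_bridges]):
        add("O", "HOH", 400 + k, lig_sites["OAR"] + 2.7 * d, "O",
            chain="W", is_het=True, is_water=True)
        add("OD1", "ASN", 100 + k, lig_sites["OAR"] + 5.4 * d, "O")
        add("CG", "ASN", 100 + k, lig_sites["OAR"] + 6.8 * d, "C")
    # two distant backbone atoms keep the protein non-empty for zero requests
    add("CA", "GLY", 200, np.array([-40.0, 40.0, 0.0]), "C")
    add("CA", "GLY", 201, np.array([-40.0, 48.0, 0.0]), "C")
    # the ligand itself
    for name, pos in lig_sites.items():
        add(name, "LIG", 701, pos, name[0], chain="L", is_het=True)

    model = Model(atoms=atoms)
    # construction check: the fixture must realize the request exactly
    table = build_interaction_table(
        model, select(model, het=True, water=False), InteractionRules())
    got = (table.counts()["HB"], table.counts()["NP"], table.counts()["ES"],
           len(table.bridges))
    if got != (n_hb, n_np, n_es, n_bridges):
        raise InfeasiblePlacementError(
            f"fixture realizes HB/NP/ES/bridges {got} instead of "
            f"{(n_hb, n_np, n_es, n_bridges)}")
    return model
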