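"""Protein-ligand interaction classification.

Heavy-atom contacts between a protein and a bound ligand are classified into
three types, following the geometric scheme used in crystallographic
recognition analyses:

* ``HB``  - hydrogen bond: donor/acceptor-complementary N/O pair at distance
  <= ``hb_max`` (3.4 A by default) passing an angle criterion at the donor;
* ``NP``  - nonpolar interaction: any other heavy-atom pair at distance
  <= ``contact_max`` (3.4 A);
* ``ES``  - electrostatic interaction: oppositely charged group atoms in the
  shell (``hb_max``, ``es_max``] (3.4-4.0 A).

Classification precedence is HB > NP > ES: the electrostatic label is
reserved for charged pairs beyond hydrogen-bonding distance, while a charged
pair inside 3.4 A that satisfies donor/acceptor complementarity is a hydrogen
bond (salt-bridge geometry).  Water-mediated hydrogen bonds are detected as
water molecules with at least one hydrogen-bond leg to the protein and one to
the ligand; each protein-water-ligand triple counts as one interaction.

Because crystal models carry no hydrogens, the hydrogen-bond angle criterion
is evaluated on heavy atoms: the angle antecedent-donor-acceptor, where the
antecedent is the donor's bonded heavy-atom neighbor, must be at least
``hb_angle_min`` (90 degrees by default; configurable).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structure_io import Model, Selection, select

__all__ = [
    "InteractionRules",
    "Contact",
    "WaterBridge",
    "InteractionTable",
    "RecognitionSummary",
    "classify_pair",
    "build_interaction_table",
    "summarize_recognition",
    "table_to_tsv",
    "table_from_tsv",
]

# Heavy-atom donor/acceptor chemistry for the 20 standard amino acids.
# Backbone N donates (except proline); backbone O/OXT accept.
_SIDECHAIN_DONORS = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("TRP", "NE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_CHARGED_POSITIVE = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
}
_CHARGED_NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}
_HIS_CHARGED = {("HIS", "ND1"), ("HIS", "NE2")}

# Default ligand atom typing (the furan-oxadiazole ureido phenoxyacetic acid
# ligand of the Keap1 complexes): carboxylate oxygens OAA/OAC are acceptors
# and charge carriers, the ureido oxygen OAB and ether/ring oxygens
# OAQ/OAR/OAO accept, the ureido nitrogens NAM/NAN donate, and the aromatic
# ring nitrogen NAP accepts.
_LIGAND_DONORS = {"NAM", "NAN"}
_LIGAND_ACCEPTORS = {"OAA", "OAB", "OAC", "OAQ", "OAR", "OAO", "NAP"}
_LIGAND_NEGATIVE = {"OAA", "OAC"}


@dataclass(frozen=True)
class InteractionRules:
    """Distance thresholds, angle criterion and atom-typing tables."""

    contact_max: float = 3.4
    hb_max: float = 3.4
    es_max: float = 4.0
    hb_angle_min: float = 90.0
    histidine_charged: bool = False
    donor_atoms: frozenset = frozenset(_SIDECHAIN_DONORS)
    acceptor_atoms: frozenset = frozenset(_SIDECHAIN_ACCEPTORS)
    charged_positive_atoms: frozenset = frozenset(_CHARGED_POSITIVE)
    charged_negative_atoms: frozenset = frozenset(_CHARGED_NEGATIVE)
    ligand_donors: frozenset = frozenset(_LIGAND_DONORS)
    ligand_acceptors: frozenset = frozenset(_LIGAND_ACCEPTORS)
    ligand_charged_negative: frozenset = frozenset(_LIGAND_NEGATIVE)
    ligand_charged_positive: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.hb_max <= self.contact_max <= self.es_max:
            raise ValueError("require hb_max <= contact_max <= es_max")

    # -- protein-side typing ------------------------------------------------

    def protein_donor(self, resname: str, name: str) -> bool:
        if name == "N" and resname != "PRO":
            return True
        return (resname, name) in self.donor_atoms

    def protein_acceptor(self, resname: str, name: str) -> bool:
        if name in ("O", "OXT"):
            return True
        return (resname, name) in self.acceptor_atoms

    def protein_positive(self, resname: str, name: str) -> bool:
        if self.histidine_charged and (resname, name) in _HIS_CHARGED:
            return True
        return (resname, name) in self.charged_positive_atoms

    def protein_negative(self, resname: str, name: str) -> bool:
        return (resname, name) in self.charged_negative_atoms

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        data = {
            "contact_max": self.contact_max,
            "hb_max": self.hb_max,
            "es_max": self.es_max,
            "hb_angle_min": self.hb_angle_min,
            "histidine_charged": self.histidine_charged,
            "donor_atoms": sorted(list(p) for p in self.donor_atoms),
            "acceptor_atoms": sorted(list(p) for p in self.acceptor_atoms),
            "charged_positive_atoms": sorted(list(p) for p in self.charged_positive_atoms),
            "charged_negative_atoms": sorted(list(p) for p in self.charged_negative_atoms),
            "ligand_donors": sorted(self.ligand_donors),
            "ligand_acceptors": sorted(self.ligand_acceptors),
            "ligand_charged_negative": sorted(self.ligand_charged_negative),
            "ligand_charged_positive": sorted(self.ligand_charged_positive),
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "InteractionRules":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = source if isinstance(source, str) else source.read()
        data = yaml.safe_load(text)
        pairs = {k: frozenset(tuple(p) for p in data[k])
                 for k in ("donor_atoms", "acceptor_atoms",
                           "charged_positive_atoms", "charged_negative_atoms")
                 if k in data}
        names = {k: frozenset(data[k])
                 for k in ("ligand_donors", "ligand_acceptors",
                           "ligand_charged_negative", "ligand_charged_positive")
                 if k in data}
        scalars = {k: data[k] for k in ("contact_max", "hb_max", "es_max",
                                        "hb_angle_min", "histidine_charged")
                   if k in data}
        return cls(**scalars, **pairs, **names)


@dataclass(frozen=True)
class Contact:
    """One classified protein-ligand heavy-atom pair."""

    protein_resname: str
    protein_resseq: int
    protein_atom: str
    ligand_atom: str
    distance: float
    itype: str  # "HB", "NP" or "ES"

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.protein_resname, self.protein_resseq)


@dataclass(frozen=True)
class WaterBridge:
    """A protein-water-ligand hydrogen-bond bridge (one interaction)."""

    protein_resname: str
    protein_resseq: int
    protein_atom: str
    water_resseq: int
    ligand_atom: str
    d_protein_water: float
    d_water_ligand: float

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.protein_resname, self.protein_resseq)


@dataclass
class InteractionTable:
    """Classified contacts and water bridges for one complex."""

    contacts: list[Contact]
    bridges: list[WaterBridge]
    form_label: str = ""

    def counts(self) -> dict[str, int]:
        out = {"HB": 0, "NP": 0, "ES": 0}
        for c in self.contacts:
            out[c.itype] += 1
        out["water_HB"] = len(self.bridges)
        return out


@dataclass(frozen=True)
class RecognitionSummary:
    """Unique recognition residues and per-type interaction counts."""

    residues: tuple[tuple[str, int], ...]
    n_residues: int
    n_hb: int
    n_water_hb: int
    n_np: int
    n_es: int


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 180.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _hb_geometry_ok(donor_xyz, acceptor_xyz, antecedent_xyz, angle_min) -> bool:
    if antecedent_xyz is None:
        return True  # no bonded antecedent known: angle criterion not applicable
    return _angle_deg(np.asarray(antecedent_xyz), np.asarray(donor_xyz),
                      np.asarray(acceptor_xyz)) >= angle_min


def classify_pair(protein_atom, ligand_atom, distance: float,
                  rules: InteractionRules,
                  geometry_context: dict | None = None) -> str | None:
    """Classify one protein-ligand atom pair; returns "HB", "NP", "ES" or None.

    ``geometry_context`` may supply bonded-antecedent coordinates for the
    angle criterion under keys ``protein_antecedent`` and
    ``ligand_antecedent``; without it the angle check is waived.
    Total function: distances beyond every threshold return ``None``.
    """
    ctx = geometry_context or {}
    p_res, p_name = protein_atom.resname, protein_atom.name
    l_name = ligand_atom.name
    p_el, l_el = protein_atom.element.upper(), ligand_atom.element.upper()

    if distance <= rules.hb_max and p_el in ("N", "O") and l_el in ("N", "O"):
        # protein donates -> ligand accepts
        if rules.protein_donor(p_res, p_name) and l_name in rules.ligand_acceptors:
            if _hb_geometry_ok(protein_atom.xyz, ligand_atom.xyz,
                               ctx.get("protein_antecedent"), rules.hb_angle_min):
                return "HB"
        # ligand donates -> protein accepts
        if l_name in rules.ligand_donors and rules.protein_acceptor(p_res, p_name):
            if _hb_geometry_ok(ligand_atom.xyz, protein_atom.xyz,
                               ctx.get("ligand_antecedent"), rules.hb_angle_min):
                return "HB"
    if distance <= rules.contact_max:
        return "NP"
    if distance <= rules.es_max:
        pos_neg = (rules.protein_positive(p_res, p_name)
                   and l_name in rules.ligand_charged_negative)
        neg_pos = (rules.protein_negative(p_res, p_name)
                   and l_name in rules.ligand_charged_positive)
        if pos_neg or neg_pos:
            return "ES"
    return None


_BOND_MAX = 2.0  # heavy-atom covalent-bond upper bound for antecedent lookup


def _antecedent_map(model: Model, indices: list[int]) -> dict[int, np.ndarray | None]:
    """Nearest same-residue heavy atom within bonding distance, per atom index."""
    by_residue: dict[tuple, list[int]] = {}
    for i, a in enumerate(model.atoms):
        if a.element.upper() == "H":
            continue
        by_residue.setdefault((a.chain, a.resseq, a.icode), []).append(i)
    out: dict[int, np.ndarray | None] = {}
    for i in indices:
        a = model.atoms[i]
        best, best_d = None, _BOND_MAX
        for j in by_residue.get((a.chain, a.resseq, a.icode), []):
            if j == i:
                continue
            d = float(np.linalg.norm(model.atoms[j].xyz - a.xyz))
            if d <= best_d:
                best, best_d = model.atoms[j].xyz, d
        out[i] = best
    return out


def _water_hb_to_protein(model, rules, water_xyz, p_idx, anteced) -> bool:
    """Water (donor+acceptor) vs protein atom: either direction qualifies."""
    a = model.atoms[p_idx]
    if a.element.upper() not in ("N", "O"):
        return False
    if rules.protein_acceptor(a.resname, a.name):
        return True  # water donates; no antecedent on the water side
    if rules.protein_donor(a.resname, a.name):
        return _hb_geometry_ok(a.xyz, water_xyz, anteced.get(p_idx),
                               rules.hb_angle_min)
    return False


def _water_hb_to_ligand(model, rules, water_xyz, l_idx, anteced) -> bool:
    a = model.atoms[l_idx]
    if a.element.upper() not in ("N", "O"):
        return False
    if a.name in rules.ligand_acceptors:
        return True
    if a.name in rules.ligand_donors:
        return _hb_geometry_ok(a.xyz, water_xyz, anteced.get(l_idx),
                               rules.hb_angle_min)
    return False


def build_interaction_table(model: Model, ligand_sel: Selection,
                            rules: InteractionRules | None = None,
                            form_label: str = "") -> InteractionTable:
    """Enumerate and classify all protein-ligand contacts of a complex.

    Protein heavy atoms within ``es_max`` of any ligand heavy atom are paired
    with it and classified by :func:`classify_pair`; water molecules with a
    hydrogen-bond leg to both sides become :class:`WaterBridge` entries.
    Each atom pair appears at most once.  Raises ``ValueError`` for an empty
    ligand selection.
    """
    rules = rules or InteractionRules()
    if len(ligand_sel) == 0:
        raise ValueError("ligand selection is empty")
    lig_idx = [i for i in ligand_sel if model.atoms[i].element.upper() != "H"]
    prot_idx = [i for i, a in enumerate(model.atoms)
                if not a.is_het and not a.is_water and a.element.upper() != "H"]
    water_idx = [i for i, a in enumerate(model.atoms)
                 if a.is_water and a.element.upper() == "O"]

    contacts: list[Contact] = []
    bridges: list[WaterBridge] = []
    coords = model.coords()
    anteced = _antecedent_map(model, prot_idx + lig_idx)

    if prot_idx:
        tree = cKDTree(coords[prot_idx])
        for li in lig_idx:
            lig_atom = model.atoms[li]
            for k in sorted(tree.query_ball_point(coords[li], rules.es_max)):
                pi = prot_idx[k]
                p_atom = model.atoms[pi]
                d = float(np.linalg.norm(coords[pi] - coords[li]))
                itype = classify_pair(
                    p_atom, lig_atom, d, rules,
                    {"protein_antecedent": anteced.get(pi),
                     "ligand_antecedent": anteced.get(li)})
                if itype is not None:
                    contacts.append(Contact(
                        protein_resname=p_atom.resname,
                        protein_resseq=p_atom.resseq,
                        protein_atom=p_atom.name,
                        ligand_atom=lig_atom.name,
                        distance=d, itype=itype))

    if water_idx and prot_idx:
        p_tree = cKDTree(coords[prot_idx])
        l_tree = cKDTree(coords[lig_idx])
        for wi in water_idx:
            w_xyz = coords[wi]
            p_legs = []
            for k in sorted(p_tree.query_ball_point(w_xyz, rules.hb_max)):
                pi = prot_idx[k]
                if _water_hb_to_protein(model, rules, w_xyz, pi, anteced):
                    p_legs.append(pi)
            if not p_legs:
                continue
            l_legs = []
            for k in sorted(l_tree.query_ball_point(w_xyz, rules.hb_max)):
                li = lig_idx[k]
                if _water_hb_to_ligand(model, rules, w_xyz, li, anteced):
                    l_legs.append(li)
            for pi in p_legs:
                for li in l_legs:
                    p_atom, l_atom = model.atoms[pi], model.atoms[li]
                    bridges.append(WaterBridge(
                        protein_resname=p_atom.resname,
                        protein_resseq=p_atom.resseq,
                        protein_atom=p_atom.name,
                        water_resseq=model.atoms[wi].resseq,
                        ligand_atom=l_atom.name,
                        d_protein_water=float(np.linalg.norm(coords[pi] - w_xyz)),
                        d_water_ligand=float(np.linalg.norm(coords[li] - w_xyz))))

    contacts.sort(key=lambda c: (c.protein_resseq, c.protein_atom, c.ligand_atom))
    bridges.sort(key=lambda b: (b.protein_resseq, b.water_resseq, b.ligand_atom))
    return InteractionTable(contacts=contacts, bridges=bridges, form_label=form_label)


def summarize_recognition(table: InteractionTable) -> RecognitionSummary:
    """Unique recognition residues (ordered by residue number) and type counts.

    Each water bridge counts once, regardless of how many hydrogen-bond legs
    it comprises.
    """
    residues: dict[tuple[str, int], None] = {}
    for item in sorted(
            [c.residue_id for c in table.contacts]
            + [b.residue_id for b in table.bridges],
            key=lambda r: r[1]):
        residues.setdefault(item)
    counts = table.counts()
    return RecognitionSummary(
        residues=tuple(residues),
        n_residues=len(residues),
        n_hb=counts["HB"],
        n_water_hb=counts["water_HB"],
        n_np=counts["NP"],
        n_es=counts["ES"],
    )


# ---------------------------------------------------------------------------
# tabular round-trip (TSV layout mirroring published recognition tables)
# ---------------------------------------------------------------------------

_TSV_HEADER = "resname\tresseq\tprotein_atom\twater\tligand_atom\ttype\tdistance"


def table_to_tsv(table: InteractionTable, path=None) -> str:
    """Serialize a table as TSV; water bridges appear as two hydrogen-bond legs."""
    lines = [_TSV_HEADER]
    for c in table.contacts:
        lines.append(f"{c.protein_resname}\t{c.protein_resseq}\t{c.protein_atom}"
                     f"\t\t{c.ligand_atom}\t{c.itype}\t{c.distance:.2f}")
    for b in table.bridges:
        w = f"W{b.water_resseq}"
        lines.append(f"{b.protein_resname}\t{b.protein_resseq}\t{b.protein_atom}"
                     f"\t{w}\t\tHB\t{b.d_protein_water:.2f}")
        lines.append(f"\t\t\t{w}\t{b.ligand_atom}\tHB\t{b.d_water_ligand:.2f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def table_from_tsv(source, form_label: str = "") -> InteractionTable:
    """Rebuild an :class:`InteractionTable` from the TSV layout above.

    A water bridge is encoded as a protein-side leg row (residue + water, no
    ligand atom) followed by a water-to-ligand leg row (water + ligand atom,
    no residue); legs sharing a water label are paired in order.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = source if isinstance(source, str) else source.read()
    contacts: list[Contact] = []
    pending: dict[str, list] = {}
    bridges: list[WaterBridge] = []
    lines = [l for l in text.splitlines() if l.strip()]
    for line in lines[1:]:
        resname, resseq, p_atom, water, l_atom, itype, dist = line.split("\t")
        d = float(dist)
        if not water:
            contacts.append(Contact(resname, int(resseq), p_atom, l_atom, d, itype))
        elif p_atom:  # protein leg of a bridge
            pending.setdefault(water, []).append((resname, int(resseq), p_atom, d))
        else:  # ligand leg: pair with the pending protein leg(s) of this water
            for pres, pseq, patom, pd in pending.get(water, []):
                bridges.append(WaterBridge(pres, pseq, patom,
                                           int(water.lstrip("W")), l_atom, pd, d))
    return InteractionTable(contacts=contacts, bridges=bridges, form_label=form_label)
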