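"""Bundled reference data.

The package ships one small curated table: the published crystallographic
recognition table of the human Keap1 Kelch domain in complex with its
furan-oxadiazole ureido phenoxyacetic acid ligand (PDB entries 3vnh, the
soaking form, and 3vng, the cocrystallization form).  It records every
classified protein-ligand interaction (hydrogen bonds, water-mediated
hydrogen bonds, nonpolar and electrostatic contacts) with heavy-atom
distances, and serves as a ground-truth fixture for the classification and
summary machinery when the deposited coordinates are not available locally.
"""

from __future__ import annotations

from importlib import resources

from .interactions import Contact, InteractionTable, WaterBridge

__all__ = ["keap1_ligand1_contact_table"]


def keap1_ligand1_contact_table(form: str) -> InteractionTable:
    """Load the curated Keap1-ligand recognition table for one crystal form.

    Parameters
    ----------
    form:
        ``"soaking"`` (PDB 3vnh) or ``"cocrystallization"`` (PDB 3vng).
    """
    if form not in ("soaking", "cocrystallization"):
        raise ValueError('form must be "soaking" or "cocrystallization"')
    text = (resources.files("bindmode") / "data" / "keap1_ligand1_contacts.tsv").read_text()
    contacts: list[Contact] = []
    bridges: list[WaterBridge] = []
    pending: dict[str, tuple] = {}
    lines = text.splitlines()
    for line in lines[1:]:
        row_form, resname, resseq, p_atom, water, l_atom, itype, dist = line.split("\t")
        if row_form != form:
            continue
        d = float(dist)
        if not water:
            contacts.append(Contact(resname, int(resseq), p_atom, l_atom, d, itype))
        elif p_atom:
            pending[water] = (resname, int(resseq), p_atom, d)
        else:
            pres, pseq, patom, pd = pending.pop(water)
            bridges.append(WaterBridge(pres, pseq, patom,
                                       int(water.lstrip("W")), l_atom, pd, d))
    return InteractionTable(contacts=contacts, bridges=bridges, form_label=form)
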