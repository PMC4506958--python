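"""Superposition RMSD between forms and the mimicry-overlap metric.

Two copies of a receptor differing by a rigid motion superpose to RMSD 0;
a perturbed copy gives the familiar sub-Angstrom value.  The mimicry metric
then asks: after anchoring two complexes on corresponding C-alpha atoms, how
far is a query ligand group (e.g. a carboxylate) from each reference group
(e.g. the glutamate carboxylates of a bound peptide motif)?  Small distance =
positional mimicry of that group.
"""

import numpy as np

import bindmode as bm
from bindmode.structure_io import AtomRecord, Model, Selection

rng = np.random.default_rng(7)
receptor = bm.make_receptor_template()
ca = bm.select(receptor, names={"CA"})

# rigid copy: RMSD 0 after fit
shifted = receptor.with_coords(receptor.coords() + np.array([10.0, -4.0, 2.0]))
print(f"rigid copy RMSD: {bm.rmsd_after_fit(receptor, shifted, ca, ca):.3f} A")

# perturbed copy: a typical between-forms C-alpha RMSD
perturbed = receptor.with_coords(
    receptor.coords() + rng.normal(scale=0.25, size=(receptor.n_atoms, 3)))
print(f"perturbed copy RMSD: {bm.rmsd_after_fit(receptor, perturbed, ca, ca):.3f} A")


def probe_atom(serial, name, xyz):
    return AtomRecord(serial=serial, name=name, altloc="", resname="PRB",
                      chain="L", resseq=900, icode="", x=xyz[0], y=xyz[1],
                      z=xyz[2], occupancy=1.0, bfactor=0.0, element="O",
                      is_het=True, is_water=False)


# reference complex: receptor + two probe groups whose centroids sit 2 A apart
g1 = np.array([[12.0, 0.0, 10.0], [13.0, 0.0, 10.0]])
g2 = g1 + np.array([2.0, 0.0, 0.0])
probes = [probe_atom(1000 + i, f"O{i + 1}", p) for i, p in enumerate(np.vstack([g1, g2]))]
ref = Model(atoms=list(receptor.atoms) + probes)
n = receptor.n_atoms
anchor_sel = bm.select(ref, names={"CA"}, het=False)
sel_g1 = Selection((n, n + 1))
sel_g2 = Selection((n + 2, n + 3))

# query: a rigidly moved copy whose probe group copies g1
R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
query = ref.with_coords(ref.coords() @ R.T + np.array([5.0, 7.0, -3.0]))
dist = bm.mimicry_overlap(ref, query, anchor_sel,
                          bm.select(query, names={"CA"}, het=False),
                          [sel_g1, sel_g2], sel_g1)
print(f"query probe to reference group 1: {dist[0]:.3f} A  (positional mimic)")
print(f"query probe to reference group 2: {dist[1]:.3f} A")
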