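"""Audit crystal-packing contacts around a bound ligand.

Builds a toy orthorhombic crystal (P2_1 2_1 2_1) in which the ligand bridges
the asymmetric molecule and one symmetry mate, then splits its contacts
(heavy-atom pairs within 3.4 A) between the two.  A large share of
symmetry-mate contacts warns that the crystallographic pose may be stabilized
by lattice packing rather than by the receptor alone.
"""

import bindmode as bm
from bindmode.structure_io import UnitCell

spec = bm.CrystalSimSpec(cell=UnitCell(60.0, 60.0, 60.0),
                         spacegroup="P 21 21 21",
                         n_sym_contacts=5, n_asu_contacts=16)
model = bm.make_crystal_fixture(spec)
ligand = bm.select(model, het=True, water=False)
report = bm.count_packing_contacts(model, ligand, cutoff=3.4)

print(f"cutoff: {report.cutoff} A")
print(f"contacts to the asymmetric molecule: {report.n_asu_contacts}")
print(f"contacts to symmetry mates:          {report.n_sym_contacts}")
for op_index, shift, n in report.per_mate:
    print(f"  operator {op_index}, lattice shift {shift}: {n} contacts")

fraction = report.n_sym_contacts / (report.n_sym_contacts + report.n_asu_contacts)
print(f"packing share of the interface: {fraction:.0%}")
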