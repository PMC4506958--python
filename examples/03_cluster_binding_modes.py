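"""Cluster a simulated trajectory into binding modes.

Simulates a 500-frame trajectory with three planted ligand binding modes at
occupancies 0.6/0.25/0.15, derives the superposition atom set from observed
contacts (excluding flip-ambiguous atoms), computes the all-pair fitted RMSD
matrix, picks a cutoff with the 70 %-of-mean heuristic's machinery (here an
explicit 0.9 A is used), and runs Daura clustering with a per-cluster report.
"""

import numpy as np

import bindmode as bm

receptor = bm.make_receptor_template()
ligand = bm.make_ligand_template()
modes = bm.binding_mode_specs(receptor, ligand, weights=(0.6, 0.25, 0.15),
                              noise_sigma=0.1)
spec = bm.TrajectorySimSpec(receptor_template=receptor, ligand_template=ligand,
                            modes=modes, n_frames=500, seed=1)
traj, labels = bm.simulate_trajectory(spec)

model = traj.frames[0]
protein = bm.select(model, het=False, water=False)
lig_sel = bm.select(model, het=True, water=False)

ts = bm.contact_timeseries(traj, protein, lig_sel)
print(f"mean contacts per frame: {ts['n_contacts'].mean():.2f}")

sel = bm.derive_superposition_atoms(traj, protein, lig_sel)
print(f"superposition atoms: {len(sel.superposition_atoms)} "
      f"({len(sel.excluded_flip_atoms)} flip-ambiguous atoms excluded)")

matrix = bm.pairwise_rmsd(traj, sel)
heur = bm.cutoff_from_mean(matrix)
print(f"mean intratrajectory RMSD: {matrix.mean_offdiagonal():.3f} A "
      f"(heuristic cutoff {heur.cutoff:.1f} A)")

cutoff = 0.9
clustering = bm.daura_cluster(matrix, cutoff)
report = bm.cluster_report(clustering, traj, sel, matrix, cutoff,
                           protein, lig_sel)
print(f"clusters holding >= 10% of {report.n_frames} frames:")
for i, c in enumerate(report.clusters, 1):
    members = sorted(clustering.clusters[i - 1].members)
    purity = np.bincount(labels[members] + 1).max() / c.size
    print(f"  cluster {i}: {c.size} frames, center frame {c.center_frame} at "
          f"{c.center_time_ps:.0f} ps, {c.contacts_per_structure:.2f} "
          f"contacts/structure, planted-mode purity {purity:.0%}")
# Cluster sizes reproduce the planted occupancies (300/125/75) because the
# inter-mode RMSD is far above the cutoff while the pose noise is far below.
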