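# bindmode

Protein–ligand binding-mode analysis for crystal structures and MD
trajectories: geometric contact classification, crystal-packing audits via
space-group symmetry expansion, and Daura RMSD clustering of trajectory
windows — plus a deterministic synthetic-data generator so the whole pipeline
runs and is testable without any external files.

## The problem

When a small molecule mediates crystal packing — as the furan-oxadiazole
ureido phenoxyacetic-acid ligand does in both crystal forms of the human
Keap1 Kelch domain (PDB 3vnh, 3vng) — the pose seen in the crystal may be
stabilized by symmetry-related protein copies rather than by the receptor
alone. The standard workflow to detect and quantify this is:

1. **Classify the crystallographic interface.** Heavy-atom protein–ligand
   pairs are typed as hydrogen bonds (donor/acceptor-complementary N/O pair,
   d ≤ 3.4 Å, donor angle criterion), nonpolar contacts (d ≤ 3.4 Å), or
   electrostatic interactions (oppositely charged groups, 3.4 < d ≤ 4.0 Å),
   with water-mediated hydrogen bonds detected as protein–water–ligand
   bridges. Precedence is HB > NP > ES, so the electrostatic label is
   reserved for charged pairs beyond hydrogen-bonding range.
2. **Audit the packing.** Expand the asymmetric unit by the space-group
   operators (P1, P2₁2₁2₁ and P6₅22 are generated in-package from tabulated
   generators) plus lattice translations, and split the ligand's contacts
   between the asymmetric molecule and symmetry mates.
3. **Cluster the solution ensemble.** On an MD trajectory window, count
   contacts per frame, derive the superposition atom set (atoms of every
   protein–ligand pair whose minimum distance over the window is ≤ 3.4 Å,
   minus flip-ambiguous atoms: Tyr/Phe CD1/CD2/CE1/CE2 and the ligand
   carboxylate oxygens), compute the all-pair Kabsch-fitted RMSD matrix
   Rᵢⱼ, choose a cutoff near 0.70·⟨Rᵢⱼ⟩ (snapped to a 0.1 Å grid), and run
   the Daura greedy algorithm: the frame with the most neighbors
   (Rᵢⱼ < cutoff) becomes a cluster center, it and its neighbors are removed,
   and the step repeats. Clusters holding ≥ 10 % of the window are reported
   with per-pair contact statistics (frequency ≥ 20 %), and the crystal pose
   is tested for membership in any cluster.
4. **Compare binding modes across complexes** with least-squares (Kabsch)
   superposition — proper rotations only, det R = +1 — and a mimicry metric:
   after anchoring two complexes on corresponding Cα atoms, the centroid
   distance from a query ligand group to each reference group (e.g. the
   glutamate carboxylates of a bound ETGE peptide).

## Worked example

`examples/03_cluster_binding_modes.py` simulates a 500-frame trajectory with
three planted binding modes (occupancies 0.6/0.25/0.15, pose noise 0.1 Å)
and runs the full clustering pipeline:

```
mean contacts per frame: 44.03
superposition atoms: 44 (5 flip-ambiguous atoms excluded)
mean intratrajectory RMSD: 3.445 A (heuristic cutoff 2.4 A)
clusters holding >= 10% of 500 frames:
  cluster 1: 300 frames, center frame 1 at 20 ps, 60.88 contacts/structure, planted-mode purity 100%
  cluster 2: 125 frames, center frame 17 at 340 ps, 27.86 contacts/structure, planted-mode purity 100%
  cluster 3: 75 frames, center frame 9 at 180 ps, 3.57 contacts/structure, planted-mode purity 100%
```

The cluster sizes reproduce the planted occupancies exactly (300/125/75 of
500) because the inter-mode RMSD is far above the cutoff while pose noise is
far below it; the per-cluster contact counts show how strongly each mode
engages the receptor. The other examples cover contact classification
against the published Keap1 recognition table (`01`), packing audits on a toy
crystal (`02`), and superposition/mimicry (`04`).

A thin CLI mirrors the library:
`bindmode io-info`, `bindmode contacts`, `bindmode packing`,
`bindmode timeseries`, `bindmode pairstats`, `bindmode cluster`,
`bindmode superpose`, `bindmode simulate` (see `--help`).

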