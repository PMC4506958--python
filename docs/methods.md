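# Methods

## Coordinate model and I/O

Structures are held as ordered lists of atom records (PDB author numbering,
taken verbatim from the file; no renumbering) with het/water flags, plus an
optional unit cell and space group. Parsing is delegated to gemmi; writing
uses an in-package fixed-column formatter so output is deterministic and
round-trips coordinate fields to 3 decimals. Alternate locations: blank or
"A" kept, others dropped (configurable); the water set is {HOH, WAT, DOD};
elements missing from the element column are inferred from the atom-name
columns. Multi-model files are trajectories: all models must share one atom
roster, and frame times are `start + i·stride` (default 20 ps stride, frame 1
at 20 ps). Coordinates are Cartesian Å everywhere; fractional coordinates
appear only inside the packing module.

Space-group operators for P1, P2₁2₁2₁ and P6₅22 are generated in-package by
closure from tabulated generators, with translations held as integers over a
denominator of 24 so composition is exact; the operator sets are verified
against gemmi's tables in the test suite, and unknown symbols fall back to
gemmi. All three groups are chiral, so every rotation has determinant +1.

## Interaction classification

Heavy-atom pairs only (crystal models carry no hydrogens; published
recognition tables list heavy atoms). Thresholds: hydrogen bond and nonpolar
cutoff 3.4 Å, electrostatic cutoff 4.0 Å, with the invariant
`hb_max ≤ contact_max ≤ es_max`. Decision order for a pair at distance d:

1. d ≤ 3.4 Å, donor/acceptor-complementary N/O pair, angle criterion passed → HB;
2. else d ≤ 3.4 Å → NP;
3. else d ≤ 4.0 Å and the atoms carry opposite formal group charges → ES;
4. else no interaction.

The precedence was chosen because, in the published Keap1 recognition table
this package reproduces, every electrostatic row lies strictly above 3.4 Å
(3.44–3.51 Å) while arginine–carboxylate pairs inside 3.4 Å appear as
hydrogen bonds (salt-bridge geometry); the test suite asserts this
consistency on the curated table.

The angle criterion works on heavy atoms: the angle antecedent–donor–acceptor
must be ≥ 90° (default; configurable), where the antecedent is the donor's
nearest bonded heavy atom in the same residue (≤ 2.0 Å). Water oxygens have
no antecedent, so water-side donation is accepted on distance alone. The 90°
default is a permissive screen for implausible geometry, not a calibrated
value; it is exposed in the rules precisely because published tables rarely
state their angle rule. Donor/acceptor typing uses a standard heavy-atom
chemistry table for the 20 amino acids (backbone N donates except proline;
backbone O/OXT accept) plus a per-ligand typing block; the default block
types the Keap1 ligand (OAA/OAC carboxylate acceptors and charge carriers,
OAB ureido acceptor, OAQ/OAR/OAO ether/ring acceptors, NAM/NAN donors, NAP
ring-nitrogen acceptor). Histidine charge is off by default and switchable.

A water bridge is one interaction (not two legs): a water with at least one
hydrogen-bond leg to the protein and one to the ligand yields one bridge per
protein-atom/water/ligand-atom triple. Each heavy-atom pair is counted once.

## Crystal packing

Ligand contacts (pairs ≤ 3.4 Å by default) are split between the asymmetric
unit and symmetry mates. Both sides count protein atoms only — waters are
excluded from the asymmetric-unit count and from mates by default (flag
available) — since the question is how the ligand touches protein molecules.
The lattice-shift search range is derived per axis from the fractional
extents of the ligand and the transformed atoms plus a distance margin
(radius × row norm of the fractionalization matrix), so molecules far from
the origin cell are handled without a hard-coded shift range. The identity
operator with zero shift (the asymmetric unit itself) is never returned as a
mate. Toy-lattice counts are verified in tests against exhaustive
enumeration over all operators × shifts in ±2 cells, and against invariance
under re-expressing the model through any space-group operator.

## Superposition

Kabsch least squares via SVD of the 3×3 covariance, reflection branch
corrected so det R = +1; equal weights (no published weighting to follow).
Configurations whose second singular value vanishes (collinear points) are
rejected as degenerate. RMSD below 1e-6 Å is reported as exactly 0. The
all-pair matrix used for clustering computes fitted RMSDs directly from
singular values of the pair covariances in a batched form, which the tests
pin against an independent quaternion-eigenvalue oracle to 1e-6 Å.

When two crystal forms are compared, atoms are matched by (residue number,
insertion code, atom name); unmatched atoms are dropped pairwise, and an
explicit residue exclusion list (rather than any auto-detection) removes
conformationally divergent termini before fitting.

The mimicry metric quantifies a comparison that is usually made visually:
after anchoring two complexes on corresponding Cα atoms, it reports the
centroid distance from a transformed query probe group (e.g. a ligand
carboxylate: the two oxygens and the carbon) to each reference probe group
(e.g. glutamate OE1/OE2/CD of a bound peptide). Centroid distance was chosen
over per-atom RMSD because probe groups may differ in size and internal
naming between a ligand and a side chain.

## Trajectory contact analysis and clustering

Contacts are counted per frame on heavy atoms by default (an
`include_hydrogens` switch exists because all-atom MD conventions vary).
Analysis windows are 1-based inclusive frame ranges; original frame numbers
and times are preserved, so frame "892" in a 501–1000 window keeps its
number. The superposition atom set is the union of atoms of every
protein–ligand pair whose minimum distance anywhere in the window is ≤ the
cutoff, minus flip-ambiguous atoms (Tyr/Phe CD1/CD2/CE1/CE2; ligand OAA/OAC;
arginine NH1/NH2 deliberately kept). Per-pair statistics report occurrence
count, frequency (percent of the window), and mean distance over contacting
frames; rows sort by count descending with ties broken by mean distance then
protein atom index, and the report filter is frequency ≥ 20 %. Rounding (2
decimals for distances, 1 for frequencies) happens only at report time.

Daura clustering uses a strict neighbor relation (RMSD < cutoff): among
unassigned frames, the frame with the most unassigned neighbors becomes a
center (ties: lowest frame index), forms a cluster with its neighbors, and
is removed; singletons are allowed, the result is a partition, and cluster
sizes are non-increasing. The cutoff heuristic is 0.70 × mean off-diagonal
RMSD snapped to the nearest 0.1 Å; the exact unsnapped value is returned
alongside, an all-zero matrix is flagged degenerate, and every entry point
accepts an explicit cutoff because published analyses search around the
heuristic value rather than adopting it blindly. Cluster reports cover
clusters holding ≥ 10 % of the window: size, center frame and time, mean
intracluster RMSD, total contacts and contacts per structure, the filtered
pair table, and — when a crystal reference is supplied — the mean member
RMSD to the crystal, the crystal-to-center RMSD, and whether the crystal
would join the cluster (center RMSD < cutoff).

## Synthetic data

The generator provides the statistical structure the analysis assumes, not
physics. The receptor is a deterministic pseudo-protein (helical backbone
trace with named side-chain pseudo-atoms, including Tyr/Phe ring carbons so
flip exclusions are exercised); the ligand is a 39-atom template (26 heavy +
13 H) carrying the contact-relevant atom names (OAA/OAB/OAC/CAT/NAM/NAN/NAP
…) in a compact, chemically non-literal geometry. Per frame the ligand pose
is one of k planted modes — a rigid transform plus per-atom isotropic
Gaussian noise (default σ = 0.1 Å) — or a dissociated placement ≥ 20 Å away
(default 50 Å) with zero contacts. Occupancies are realized exactly by
largest-remainder apportionment followed by a seeded shuffle, so planted
cluster sizes are known to within rounding; draws are i.i.d. with no Markov
kinetics. One explicit seeded generator per simulation call; identical seeds
give byte-identical trajectories. Default study conditions follow the
published analysis design: 500-frame windows at 20 ps stride, report
thresholds of 10 % (cluster size) and 20 % (pair frequency), contact cutoff
3.4 Å.

What passing tests show — and do not show. The generator's frames are
i.i.d. rigid poses with isotropic noise around a rigid receptor; real
trajectories have correlated frames, internal ligand flexibility and
receptor motion. Pipeline tests on synthetic data therefore validate the
bookkeeping and the algorithms (selection, RMSD, clustering, statistics)
under known ground truth, not force-field realism or the numerical values of
any real system's cluster sizes.

Crystal fixtures place wide-spaced (8 Å grid) protein pseudo-atoms in a
requested cell and put ligand atoms at an exact contact distance from chosen
symmetry-mate images; every construction is verified by exhaustive
enumeration before being returned, and unrealizable requests raise an error.
Interaction fixtures realize exact HB/NP/ES/bridge counts using four
spatially isolated sites (≥ 25 Å apart) with golden-spiral directions around
each site so added units never create stray pairs.

## Numerical choices and limitations

* Zero-RMSD tolerance 1e-6 Å; matrix symmetry tolerance 1e-9.
* Cutoff snapping is nearest-multiple (Python banker's rounding at exact
  midpoints, which never arise on the 0.1 Å grid with measured means).
* Antecedent lookup uses a 2.0 Å same-residue bond bound; unusual covalent
  geometry (metal sites, modified residues) is out of scope.
* π-stacking, cation-π, halogen bonds, protonation prediction, and
  explicit-hydrogen hydrogen-bond geometry are not modeled.
* Trajectory input is multi-model PDB only; binary formats (DCD/XTC) are
  extension points.
* The deposited-entry checks in the acceptance tests need the three PDB
  files locally (they are not redistributable in-repo); all other tests are
  self-contained.
* Residue ranges follow the coordinates as found in the file; selections
  never guess about residues absent from the model.
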