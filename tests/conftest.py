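import numpy as np
import pytest

import bindmode as bm
from bindmode.structure_io import AtomRecord, Model, Trajectory


def toy_atom(serial, name, resname, resseq, xyz, element, *, chain="A",
             is_het=False, is_water=False, altloc=""):
    return AtomRecord(serial=serial, name=name, altloc=altloc, resname=resname,
                      chain=chain, resseq=resseq, icode="",
                      x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                      occupancy=1.0, bfactor=0.0, element=element,
                      is_het=is_het, is_water=is_water)


def pair_model(n_pairs):
    """n protein carbons (GLY CA) plus n ligand carbons, coordinates all zero."""
    atoms = [toy_atom(i + 1, "CA", "GLY", 10 + i, (0, 0, 0), "C")
             for i in range(n_pairs)]
    atoms += [toy_atom(n_pairs + j + 1, f"C{j + 1}", "LIG", 701, (0, 0, 0), "C",
                       chain="L", is_het=True) for j in range(n_pairs)]
    return Model(atoms=atoms)


def pair_trajectory(distances):
    """Trajectory over a pair model; ``distances`` is (n_frames, n_pairs).

    Protein atom i sits at (40*i, 0, 0); ligand atom i sits ``distances[f, i]``
    along +y from it, so pair i is the only pair each ligand atom can touch.
    """
    distances = np.asarray(distances, dtype=float)
    n_frames, n_pairs = distances.shape
    template = pair_model(n_pairs)
    frames = []
    for f in range(n_frames):
        coords = np.zeros((2 * n_pairs, 3))
        for i in range(n_pairs):
            coords[i] = (40.0 * i, 0.0, 0.0)
            coords[n_pairs + i] = (40.0 * i, distances[f, i], 0.0)
        frames.append(template.with_coords(coords))
    return Trajectory(frames=frames, times=20.0 * np.arange(1, n_frames + 1))


@pytest.fixture(scope="session")
def receptor():
    return bm.make_receptor_template()


@pytest.fixture(scope="session")
def ligand():
    return bm.make_ligand_template()


@pytest.fixture(scope="session")
def two_mode_run(receptor, ligand):
    """500-frame, two-mode (0.6/0.4) simulation, seed 1, noise 0.1 A."""
    modes = bm.binding_mode_specs(receptor, ligand, weights=(0.6, 0.4),
                                  noise_sigma=0.1)
    spec = bm.TrajectorySimSpec(receptor_template=receptor,
                                ligand_template=ligand, modes=modes,
                                n_frames=500, seed=1)
    traj, labels = bm.simulate_trajectory(spec)
    return traj, labels


@pytest.fixture(scope="session")
def three_mode_run(receptor, ligand):
    """500-frame, three-mode (0.6/0.25/0.15) simulation, seed 1."""
    modes = bm.binding_mode_specs(receptor, ligand, weights=(0.6, 0.25, 0.15),
                                  noise_sigma=0.1)
    spec = bm.TrajectorySimSpec(receptor_template=receptor,
                                ligand_template=ligand, modes=modes,
                                n_frames=500, seed=1)
    traj, labels = bm.simulate_trajectory(spec)
    return traj, labels


@pytest.fixture(scope="session")
def three_mode_clustering(three_mode_run):
    traj, labels = three_mode_run
    model = traj.frames[0]
    protein = bm.select(model, het=False, water=False)
    lig_sel = bm.select(model, het=True, water=False)
    spec = bm.derive_superposition_atoms(traj, protein, lig_sel)
    matrix = bm.pairwise_rmsd(traj, spec)
    clustering = bm.daura_cluster(matrix, 0.9)
    return traj, labels, spec, matrix, clustering
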