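import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bindmode as bm
from bindmode.clustering import RmsdMatrix, daura_cluster, cutoff_from_mean
from bindmode.structure_io import Selection, Trajectory
from conftest import pair_trajectory
from _oracles import exhaustive_daura, quaternion_rmsd, random_rigid_transform

RNG = np.random.default_rng(11)


def _random_matrix(rng, n):
    a = rng.uniform(0.0, 3.0, size=(n, n))
    vals = (a + a.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return RmsdMatrix(values=vals)


class TestPairwiseRmsd:
    def test_identical_frames_give_zero_matrix(self):
        traj = pair_trajectory(np.full((4, 3), 3.0))
        sel = Selection(tuple(range(6)))
        m = bm.pairwise_rmsd(traj, sel)
        assert np.allclose(m.values, 0.0)

    def test_rigid_motion_between_frames_is_removed(self, receptor):
        R, t = random_rigid_transform(RNG)
        moved = receptor.with_coords(receptor.coords() @ R.T + t)
        traj = Trajectory(frames=[receptor, moved], times=[20.0, 40.0])
        sel = bm.select(receptor, names={"CA"})
        m = bm.pairwise_rmsd(traj, sel)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_oracle_per_pair(self, receptor):
        frames = [receptor.with_coords(receptor.coords()
                                       + RNG.normal(scale=0.8, size=(receptor.n_atoms, 3)))
                  for _ in range(5)]
        traj = Trajectory(frames=frames, times=20.0 * np.arange(1, 6))
        sel = bm.select(receptor, names={"CA"})
        m = bm.pairwise_rmsd(traj, sel)
        X = traj.coords(sel)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    quaternion_rmsd(X[i], X[j]), abs=1e-6)

    def test_too_few_atoms(self):
        traj = pair_trajectory(np.full((2, 1), 3.0))
        with pytest.raises(ValueError, match="at least 3"):
            bm.pairwise_rmsd(traj, Selection((0, 1)))


class TestCutoffHeuristic:
    def test_printed_mean_snaps_to_published_cutoff(self):
        m = RmsdMatrix(values=np.array([[0.0, 1.232], [1.232, 0.0]]))
        res = cutoff_from_mean(m, fraction=0.70, grid=0.1)
        assert res.cutoff == pytest.approx(0.9)
        assert res.exact == pytest.approx(0.8624)
        assert not res.degenerate

    def test_plain_arithmetic(self):
        m = RmsdMatrix(values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert cutoff_from_mean(m, fraction=0.5).cutoff == pytest.approx(1.0)
        assert bm.snap_cutoff(2.0, 0.5, 0.1) == pytest.approx(1.0)

    def test_all_zero_matrix_flags_degenerate(self):
        m = RmsdMatrix(values=np.zeros((3, 3)))
        res = cutoff_from_mean(m)
        assert res.cutoff == 0.0 and res.degenerate

    def test_single_frame_is_an_error(self):
        with pytest.raises(ValueError):
            cutoff_from_mean(RmsdMatrix(values=np.zeros((1, 1))))

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            RmsdMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            RmsdMatrix(values=np.array([[1.0]]))


class TestDauraCluster:
    def test_identical_frames_form_one_cluster_centered_lowest(self):
        m = RmsdMatrix(values=np.zeros((6, 6)))
        cl = daura_cluster(m, 0.5)
        assert cl.n_clusters == 1
        assert cl.clusters[0].center == 0
        assert cl.clusters[0].members == frozenset(range(6))

    def test_two_planted_blocks(self):
        n1, n2 = 7, 4
        vals = np.full((n1 + n2, n1 + n2), 5.0)
        vals[:n1, :n1] = 0.2
        vals[n1:, n1:] = 0.2
        np.fill_diagonal(vals, 0.0)
        cl = daura_cluster(RmsdMatrix(values=vals), 0.9)
        assert [sorted(c.members) for c in cl.clusters] == \
               [list(range(n1)), list(range(n1, n1 + n2))]

    def test_strict_inequality_at_the_cutoff(self):
        vals = np.array([[0.0, 0.9], [0.9, 0.0]])
        cl = daura_cluster(RmsdMatrix(values=vals), 0.9)
        assert cl.n_clusters == 2  # 0.9 is not < 0.9

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            daura_cluster(RmsdMatrix(values=np.zeros((2, 2))), 0.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        m = _random_matrix(rng, n)
        cutoff = float(rng.uniform(0.3, 2.5))
        ours = [(c.center, set(c.members)) for c in daura_cluster(m, cutoff).clusters]
        assert ours == exhaustive_daura(m.values, cutoff)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=10 ** 6),
           st.floats(min_value=0.05, max_value=3.0))
    def test_partition_and_center_optimality(self, n, seed, cutoff):
        m = _random_matrix(np.random.default_rng(seed), n)
        cl = daura_cluster(m, cutoff)
        seen = set()
        sizes = []
        remaining = set(range(n))
        for c in cl.clusters:
            assert c.center in c.members
            assert not (c.members & seen), "clusters overlap"
            # center optimality among frames still unassigned at selection time
            counts = {i: sum(1 for j in remaining if j != i and m.values[i, j] < cutoff)
                      for i in remaining}
            assert counts[c.center] == max(counts.values())
            seen |= c.members
            remaining -= c.members
            sizes.append(len(c.members))
        assert seen == set(range(n))
        assert sizes == sorted(sizes, reverse=True)


class TestPlantedModes:
    def test_recovers_planted_occupancies(self, three_mode_clustering):
        traj, labels, spec, matrix, clustering = three_mode_clustering
        sizes = sorted((len(c.members) for c in clustering.clusters), reverse=True)
        assert abs(sizes[0] - 300) <= 2
        assert abs(sizes[1] - 125) <= 2
        assert abs(sizes[2] - 75) <= 2
        for c in clustering.clusters[:3]:
            members = sorted(c.members)
            _, counts = np.unique(labels[members], return_counts=True)
            assert counts.max() == len(members)  # pure clusters


class TestClusterReport:
    def test_report_blocks(self, three_mode_clustering, receptor, ligand):
        traj, labels, spec, matrix, clustering = three_mode_clustering
        model = traj.frames[0]
        protein = bm.select(model, het=False, water=False)
        lig_sel = bm.select(model, het=True, water=False)
        # a "crystal" pose planted far from every simulated mode
        far = np.vstack([receptor.coords(),
                         ligand.coords() + np.array([0.0, -30.0, 10.0])])
        crystal = bm.Model(atoms=list(receptor.atoms) + list(ligand.atoms)
                           ).with_coords(far)
        report = bm.cluster_report(clustering, traj, spec, matrix, 0.9,
                                   protein, lig_sel, crystal_ref=crystal)
        assert report.n_frames == 500
        # only clusters holding at least 10 % of the window are listed
        assert all(c.size >= 50 for c in report.clusters)
        assert len(report.clusters) == 3
        for c in report.clusters:
            assert c.crystal_joins is False
            assert c.crystal_to_center_rmsd > 0.9
            assert c.contacts_per_structure == pytest.approx(c.total_contacts / c.size)
            assert (c.pair_stats["frequency"] >= 20.0).all()
        d = report.to_dict()
        assert len(d["clusters"]) == 3

    def test_identical_frames_have_zero_intracluster_rmsd(self):
        traj = pair_trajectory(np.full((5, 3), 3.0))
        sel = Selection(tuple(range(6)))
        matrix = bm.pairwise_rmsd(traj, sel)
        clustering = daura_cluster(matrix, 0.5)
        model = traj.frames[0]
        report = bm.cluster_report(clustering, traj, sel, matrix, 0.5,
                                   bm.select(model, het=False, water=False),
                                   bm.select(model, het=True, water=False))
        assert report.clusters[0].mean_intracluster_rmsd == 0.0
        assert report.clusters[0].size == 5
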