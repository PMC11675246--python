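"""Trajectory bookkeeping, superposition, RMSD/RMSF, DCC, and clustering."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import f8landscape as f8
from f8landscape import dynamics as dyn
from f8landscape.errors import BookkeepingError, DegenerateStructureError, LabelError


def _traj(coords, chain="A"):
    coords = np.asarray(coords, dtype=float)
    labels = [(chain, i + 1, "ALA") for i in range(coords.shape[1])]
    return f8.Trajectory(coords=coords, labels=labels)


def _random_traj(n_frames, n_res, seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_res, 3)) * 8
    return _traj(base[None] + rng.normal(size=(n_frames, n_res, 3)))


def dcc_oracle(coords):
    """Naive O(N^2 T) double-loop DCC for cross-checking."""
    T, N, _ = coords.shape
    mean = coords.mean(axis=0)
    d = coords - mean
    C = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            num = sum(float(d[t, i] @ d[t, j]) for t in range(T)) / T
            vi = sum(float(d[t, i] @ d[t, i]) for t in range(T)) / T
            vj = sum(float(d[t, j] @ d[t, j]) for t in range(T)) / T
            C[i, j] = num / np.sqrt(vi * vj)
    return C


class TestExpectedFrames:
    @pytest.mark.parametrize("ns,ps,expected", [(80, 100, 801), (0, 100, 1), (1, 100, 11)])
    def test_frame_counts(self, ns, ps, expected):
        assert f8.expected_frames(ns, ps) == expected

    def test_non_divisible_interval_raises(self):
        with pytest.raises(BookkeepingError):
            f8.expected_frames(1, 300)


class TestSuperpose:
    def test_rigid_copies_collapse_to_identical_frames(self):
        rng = np.random.default_rng(41)
        base = rng.normal(size=(12, 3)) * 6
        frames = []
        for k in range(15):
            R = Rotation.random(rng=np.random.default_rng(k)).as_matrix()
            frames.append(base @ R.T + rng.normal(size=3) * 20)
        sup = f8.superpose(_traj(frames))
        assert np.abs(sup.coords - sup.coords[0]).max() < 1e-9

    def test_already_aligned_trajectory_unchanged(self):
        t = _random_traj(20, 10, seed=42)
        sup = f8.superpose(t)
        sup2 = f8.superpose(sup)
        assert np.abs(sup2.coords - sup.coords).max() < 1e-8

    def test_intra_frame_distances_preserved(self):
        t = _random_traj(10, 8, seed=43)
        sup = f8.superpose(t)
        for before, after in zip(t.coords, sup.coords):
            db = np.linalg.norm(before[:, None] - before[None], axis=2)
            da = np.linalg.norm(after[:, None] - after[None], axis=2)
            np.testing.assert_allclose(da, db, atol=1e-9)

    def test_rmsd_not_increased_by_superposition(self):
        rng = np.random.default_rng(44)
        base = rng.normal(size=(10, 3)) * 6
        frames = []
        for k in range(25):
            R = Rotation.random(rng=np.random.default_rng(100 + k)).as_matrix()
            wob = base + rng.normal(scale=0.5, size=base.shape)
            frames.append(wob @ R.T + rng.normal(size=3) * 5)
        t = _traj(frames)
        ref = t.coords[0]
        before = f8.rmsd_series(t, reference=ref)
        sup = f8.superpose(t, reference=ref)
        after = f8.rmsd_series(sup, reference=ref)
        assert np.all(after <= before + 1e-9)

    def test_collinear_geometry_raises(self):
        coords = np.zeros((5, 4, 3))
        coords[:, :, 0] = np.arange(4)  # all residues on the x axis
        with pytest.raises(DegenerateStructureError):
            f8.superpose(_traj(coords))

    def test_batched_kabsch_matches_scipy(self):
        rng = np.random.default_rng(45)
        coords = rng.normal(size=(30, 9, 3)) * 5
        target = rng.normal(size=(9, 3)) * 5
        batch = dyn._kabsch_align_batch(coords, target)
        ref = np.stack([dyn._kabsch_align(f, target) for f in coords])
        np.testing.assert_allclose(batch, ref, atol=1e-10)


class TestRmsdRmsf:
    def test_frame_identical_to_reference_has_zero_rmsd(self):
        t = _random_traj(5, 6, seed=46)
        r = f8.rmsd_series(t, reference=t.coords[2])
        assert r[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_displacement(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 3.0
        t = _traj(coords)
        r = f8.rmsd_series(t, reference=coords[0])
        assert r[1] == pytest.approx(3.0)

    def test_static_residue_has_zero_rmsf(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = np.sin(np.arange(10))
        rmsf = f8.rmsf_per_residue(_traj(coords))
        assert rmsf[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_oscillation_rmsf_equals_amplitude(self):
        a = 1.7
        coords = np.zeros((8, 1, 3))
        coords[::2, 0, 2] = a
        coords[1::2, 0, 2] = -a
        assert f8.rmsf_per_residue(_traj(coords))[0] == pytest.approx(a)

    def test_match_brute_force_loops(self):
        t = _random_traj(30, 7, seed=47)
        ref = t.mean_structure()
        rmsd_brute = [
            np.sqrt(np.mean([np.sum((t.coords[k, i] - ref[i]) ** 2)
                             for i in range(t.n_residues)]))
            for k in range(t.n_frames)
        ]
        np.testing.assert_allclose(f8.rmsd_series(t), rmsd_brute, atol=1e-12)
        rmsf_brute = [
            np.sqrt(np.mean([np.sum((t.coords[k, i] - ref[i]) ** 2)
                             for k in range(t.n_frames)]))
            for i in range(t.n_residues)
        ]
        np.testing.assert_allclose(f8.rmsf_per_residue(t), rmsf_brute, atol=1e-12)


class TestDcc:
    def test_unit_diagonal_and_symmetry(self):
        m = f8.dcc(_random_traj(40, 10, seed=48))
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_identical_and_mirrored_series(self):
        rng = np.random.default_rng(49)
        d = rng.normal(size=(20, 1, 3))
        coords = np.concatenate([d, d, -d], axis=1)
        m = f8.dcc(_traj(coords))
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self):
        for seed in (50, 51, 52):
            t = _random_traj(60, 12, seed=seed)
            np.testing.assert_allclose(
                f8.dcc(t).values, dcc_oracle(t.coords), atol=1e-10
            )

    def test_zero_fluctuation_residue_flagged_not_zeroed(self):
        coords = np.zeros((10, 3, 3))
        coords[:, 0] = np.random.default_rng(53).normal(size=(10, 3))
        coords[:, 1] = coords[:, 0] * 0.5 + 1
        # residue 2 never moves
        m = f8.dcc(_traj(coords))
        assert m.undefined[2]
        assert np.isnan(m.values[2, 0]) and np.isnan(m.values[0, 2])
        assert not np.isnan(m.values[0, 1])

    def test_invariant_under_global_rigid_motion(self):
        t = _random_traj(30, 8, seed=54)
        R = Rotation.random(rng=np.random.default_rng(7)).as_matrix()
        moved = _traj(t.coords @ R.T + np.array([5.0, -3.0, 12.0]))
        m0 = f8.dcc(f8.superpose(t))
        m1 = f8.dcc(f8.superpose(moved))
        np.testing.assert_allclose(m0.values, m1.values, atol=1e-8)

    def test_block_target_recovered(self):
        t = f8.make_trajectory(
            f8.TrajectorySpec(n_frames=5000, n_residues=50,
                              correlation_blocks=[(list(range(5)), 0.9)], seed=55)
        )
        m = f8.dcc(t)
        pairs = [m.values[i, j] for i, j in itertools.combinations(range(5), 2)]
        assert abs(np.mean(pairs) - 0.9) < 0.05


class TestCorrelationSummary:
    def _matrix_from_fixture(self, bundle):
        """Build a DCC matrix holding the printed partner correlations of the
        most-connected uncertain residue (I2100)."""
        rows = bundle.cluster_correlations
        sub = rows[(rows["cluster"] == 1) & (rows["vus_residue"] == "I2100")]
        labels = [("A", 2100, "ILE")] + [
            ("A", int(r.partner_resnum), str(r.partner_aa)) for r in sub.itertuples()
        ]
        n = len(labels)
        vals = np.eye(n)
        for k, r in enumerate(sub.itertuples(), start=1):
            vals[0, k] = vals[k, 0] = float(r.correlation)
        return dyn.DCCMatrix(values=vals, labels=labels), len(sub)

    def test_printed_partner_list_all_above_point_nine(self, fixtures_bundle):
        matrix, n_partners = self._matrix_from_fixture(fixtures_bundle)
        assert n_partners == 21
        pathogenic = [(c, r) for c, r, _aa in matrix.labels[1:]]
        (s,) = f8.correlation_summary(matrix, [("A", 2100)], pathogenic,
                                      thresholds=(0.8, 0.85, 0.9))
        assert s.pathogenic_counts[0.9] == 21
        assert s.top_pathogenic[0][1] == pytest.approx(0.984)

    def test_impossible_threshold_counts_zero(self, fixtures_bundle):
        matrix, _n = self._matrix_from_fixture(fixtures_bundle)
        pathogenic = [(c, r) for c, r, _aa in matrix.labels[1:]]
        (s,) = f8.correlation_summary(matrix, [("A", 2100)], pathogenic,
                                      thresholds=(1.01,))
        assert s.pathogenic_counts[1.01] == 0

    def test_counts_match_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(56)
        for _ in range(5):
            n = 15
            A = rng.uniform(-1, 1, size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            labels = [("A", i + 1, "ALA") for i in range(n)]
            m = dyn.DCCMatrix(values=A, labels=labels)
            vus = [("A", 3)]
            pathogenic = [("A", i + 1) for i in range(n) if i != 2]
            ths = (0.2, 0.5, 0.8)
            (s,) = f8.correlation_summary(m, vus, pathogenic, thresholds=ths)
            for th in ths:
                brute = sum(1 for i in range(n) if i != 2 and A[2, i] >= th)
                assert s.pathogenic_counts[th] == brute

    def test_counts_non_increasing_in_threshold(self, fixtures_bundle):
        matrix, _n = self._matrix_from_fixture(fixtures_bundle)
        pathogenic = [(c, r) for c, r, _aa in matrix.labels[1:]]
        (s,) = f8.correlation_summary(matrix, [("A", 2100)], pathogenic)
        counts = [s.pathogenic_counts[t] for t in sorted(s.pathogenic_counts)]
        assert counts == sorted(counts, reverse=True)

    def test_partner_chain_restriction(self):
        labels = [("A", 1, "ALA"), ("A", 2, "ALA"), ("V", 700, "LEU")]
        vals = np.array([[1.0, 0.95, 0.9], [0.95, 1.0, 0.2], [0.9, 0.2, 1.0]])
        m = dyn.DCCMatrix(values=vals, labels=labels)
        (s,) = f8.correlation_summary(m, [("A", 1)], [("A", 2)], partner_chain="V",
                                      thresholds=(0.8,))
        assert s.partner_counts[0.8] == 1
        assert s.top_partner[0][0] == ("V", 700, "LEU")

    def test_unknown_residue_raises(self):
        m = dyn.DCCMatrix(values=np.eye(2),
                          labels=[("A", 1, "ALA"), ("A", 2, "ALA")])
        with pytest.raises(LabelError):
            f8.correlation_summary(m, [("A", 99)], [])


class TestClusterTopVus:
    def test_two_close_residues_one_cluster(self):
        coords = {("A", 1): np.zeros(3), ("A", 2): np.array([5.0, 0, 0])}
        out = f8.cluster_top_vus(coords, [("A", 1), ("A", 2)], cutoff_angstrom=12)
        assert out[("A", 1)] == out[("A", 2)]

    def test_all_far_apart_all_singletons(self):
        coords = {("A", i): np.array([i * 100.0, 0, 0]) for i in range(1, 5)}
        out = f8.cluster_top_vus(coords, list(coords), cutoff_angstrom=12)
        assert len(set(out.values())) == 4

    def test_missing_coordinate_raises(self):
        with pytest.raises(LabelError):
            f8.cluster_top_vus({}, [("A", 1)])

    @staticmethod
    def brute_force_components(pts, cutoff):
        n = len(pts)
        seen, comps = set(), 0
        adj = np.linalg.norm(pts[:, None] - pts[None], axis=2) <= cutoff
        for s in range(n):
            if s in seen:
                continue
            comps += 1
            stack = [s]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(v for v in range(n) if adj[u, v] and v not in seen)
        return comps

    def test_component_count_matches_graph_search(self):
        rng = np.random.default_rng(57)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            pts = rng.uniform(0, 60, size=(n, 3))
            coords = {("A", i + 1): pts[i] for i in range(n)}
            res = list(coords)
            out = f8.cluster_top_vus(coords, res, cutoff_angstrom=15)
            assert len(set(out.values())) == self.brute_force_components(pts, 15)

    def test_cluster_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(58)
        pts = rng.uniform(0, 50, size=(12, 3))
        coords = {("A", i + 1): pts[i] for i in range(12)}
        res = list(coords)
        counts = [len(set(f8.cluster_top_vus(coords, res, c).values()))
                  for c in (5, 10, 20, 40, 80)]
        assert counts == sorted(counts, reverse=True)


class TestTrajectoryIO:
    def test_pdb_round_trip(self, tmp_path):
        t = _random_traj(4, 5, seed=59)
        p = tmp_path / "traj.pdb"
        t.to_pdb(p)
        back = f8.Trajectory.from_pdb(p)
        np.testing.assert_allclose(back.coords, t.coords, atol=1e-3)  # PDB precision
        assert back.labels == t.labels

    def test_pdb_readable_by_mdanalysis(self, tmp_path):
        """The multi-model PDB output parses identically in MDAnalysis."""
        mda = pytest.importorskip("MDAnalysis")
        t = _random_traj(3, 6, seed=61)
        p = tmp_path / "traj.pdb"
        t.to_pdb(p)
        u = mda.Universe(str(p))
        assert len(u.trajectory) == t.n_frames
        assert u.atoms.n_atoms == t.n_residues
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        np.testing.assert_allclose(coords, t.coords, atol=1e-3)
        assert list(u.atoms.resids) == [r for _c, r, _aa in t.labels]

    def test_tsv_round_trip(self, tmp_path):
        t = _random_traj(3, 4, seed=60)
        p = tmp_path / "traj.tsv"
        t.to_tsv(p)
        back = f8.Trajectory.from_tsv(p)
        np.testing.assert_allclose(back.coords, t.coords, atol=1e-9)
        assert back.labels == t.labels
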