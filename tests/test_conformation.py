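"""Superposition, gromos clustering, GNM modes and hinge detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mfe2dh import (
    daura_cluster,
    detect_hinges,
    gnm_modes,
    kabsch_superpose,
    middle_structure,
    pairwise_rmsd,
)
from mfe2dh.conformation import ClusterResult
from mfe2dh.structure import Frame, Topology, Trajectory


def _ca_frame(coords, resnums=None, chain="A"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    top = Topology([chain] * n, resnums, ["GLY"] * n, ["CA"] * n)
    return Frame(top, coords)


def _ca_traj(frame_coords):
    frames = [_ca_frame(c) for c in frame_coords]
    return Trajectory(
        frames[0].topology,
        np.stack([f.coords for f in frames]),
        np.arange(len(frames), dtype=float),
    )


@pytest.fixture(scope="module")
def blob():
    rng = np.random.default_rng(5)
    return rng.uniform(-3, 3, size=(8, 3))


class TestKabsch:
    def test_identity_rmsd_zero(self, blob):
        f = _ca_frame(blob)
        _, rmsd = kabsch_superpose(f, f)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, blob):
        f = _ca_frame(blob)
        rot = Rotation.from_euler("xyz", [30, -45, 80], degrees=True)
        moved = _ca_frame(rot.apply(blob) + np.array([5.0, -2.0, 3.0]))
        fitted, rmsd = kabsch_superpose(moved, f)
        assert rmsd < 1e-6
        assert np.abs(fitted.coords - blob).max() < 1e-6

    def test_matches_rotation_grid_search(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        _, rmsd = kabsch_superpose(_ca_frame(a), _ca_frame(b))
        # independent oracle: dense grid over Euler angles
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        angles = np.linspace(0, 2 * np.pi, 25, endpoint=False)
        best = np.inf
        for x in angles:
            for y in angles[:13]:  # beta in [0, pi)
                for z in angles:
                    R = Rotation.from_euler("ZYX", [x, y, z]).as_matrix()
                    d = bc - ac @ R.T
                    best = min(best, np.sqrt((d**2).sum() / 4))
        assert rmsd <= best + 1e-9
        assert best - rmsd < 0.05

    def test_mismatched_selection_sizes_rejected(self, blob):
        with pytest.raises(ValueError):
            kabsch_superpose(_ca_frame(blob), _ca_frame(blob[:-1]))

    def test_rotation_is_proper(self, blob):
        # a reflected copy must be fitted by rotation only (det +1), not a mirror
        mirrored = blob * np.array([-1.0, 1.0, 1.0])
        _, rmsd = kabsch_superpose(_ca_frame(mirrored), _ca_frame(blob))
        assert rmsd > 0.1


def _brute_daura(rmsd_matrix, cutoff):
    """Reference implementation: explicit neighbour-count simulation."""
    n = rmsd_matrix.shape[0]
    remaining = set(range(n))
    clusters, centers = [], []
    while remaining:
        counts = {
            i: sum(1 for j in remaining if rmsd_matrix[i, j] <= cutoff)
            for i in remaining
        }
        center = min(remaining, key=lambda i: (-counts[i], i))
        members = sorted(j for j in remaining if rmsd_matrix[center, j] <= cutoff)
        clusters.append(members)
        centers.append(center)
        remaining -= set(members)
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), k))
    return [clusters[k] for k in order], [centers[k] for k in order]


class TestDauraClustering:
    def test_identical_frames_single_cluster(self, blob):
        traj = _ca_traj([blob] * 6)
        res = daura_cluster(traj, cutoff=0.5)
        assert res.n_clusters == 1
        assert sorted(res.clusters[0]) == list(range(6))
        assert res.centers[0] == 0  # lowest index on ties

    def test_tiny_cutoff_singletons(self, blob):
        rng = np.random.default_rng(2)
        traj = _ca_traj([blob + rng.normal(0, 0.5, blob.shape) for _ in range(5)])
        mat = pairwise_rmsd(traj)
        res = daura_cluster(traj, cutoff=0.9 * mat[mat > 0].min())
        assert res.n_clusters == 5
        assert all(len(c) == 1 for c in res.clusters)

    def test_two_basin_partition_matches_bruteforce(self, blob):
        rng = np.random.default_rng(3)
        shifted = blob.copy()
        shifted[:4] += 3.0  # deform half the atoms -> distinct conformer
        frames = [blob + rng.normal(0, 0.05, blob.shape) for _ in range(6)]
        frames += [shifted + rng.normal(0, 0.05, blob.shape) for _ in range(4)]
        traj = _ca_traj(frames)
        mat = pairwise_rmsd(traj)
        cutoff = 1.0
        res = daura_cluster(traj, cutoff=cutoff)
        exp_clusters, exp_centers = _brute_daura(mat, cutoff)
        assert [sorted(c) for c in res.clusters] == exp_clusters
        assert res.centers == exp_centers
        # partition property
        flat = sorted(f for c in res.clusters for f in c)
        assert flat == list(range(10))

    def test_removing_largest_cluster_is_self_consistent(self, blob):
        rng = np.random.default_rng(8)
        frames = [blob + rng.normal(0, 0.4, blob.shape) for _ in range(8)]
        traj = _ca_traj(frames)
        res = daura_cluster(traj, cutoff=0.8)
        sizes = [len(c) for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)
        mat = pairwise_rmsd(traj)
        exp_clusters, _ = _brute_daura(mat, 0.8)
        assert [sorted(c) for c in res.clusters] == exp_clusters


class TestMiddleStructure:
    def test_singleton_cluster(self, blob):
        traj = _ca_traj([blob, blob + 10.0])
        res = ClusterResult(clusters=[[1], [0]], centers=[1, 0], cutoff=0.1)
        assert middle_structure(traj, res).time == traj[1].time

    def test_minimal_summed_rmsd_member(self, blob):
        # A and C sit 2*d from each other, B halfway: B minimizes summed RMSD
        shift = np.zeros_like(blob)
        shift[0] = [1.0, 0, 0]
        frames = [blob, blob + 0.5 * shift, blob + 1.0 * shift]
        traj = _ca_traj(frames)
        res = daura_cluster(traj, cutoff=10.0)
        mid = middle_structure(traj, res)
        sums = pairwise_rmsd(traj).sum(axis=1)
        assert np.allclose(mid.coords, traj[int(np.argmin(sums))].coords)
        assert int(np.argmin(sums)) == 1

    def test_tie_breaks_to_lowest_index(self, blob):
        traj = _ca_traj([blob] * 4)
        res = daura_cluster(traj, cutoff=0.5)
        assert middle_structure(traj, res).time == traj[0].time


class TestGnm:
    def test_k3_eigenvalues(self):
        # 3 mutually connected nodes: graph Laplacian of K3 has spectrum {0, 3, 3}
        f = _ca_frame([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        gnm = gnm_modes(f, cutoff=5.0)
        assert np.allclose(gnm.eigenvalues, [0.0, 3.0, 3.0], atol=1e-9)

    def test_kirchhoff_rows_sum_to_zero(self, blob):
        gnm = gnm_modes(_ca_frame(blob), cutoff=6.0)
        assert np.allclose(gnm.kirchhoff.sum(axis=1), 0.0)

    def test_uniform_vector_in_null_space(self, blob):
        gnm = gnm_modes(_ca_frame(blob), cutoff=10.0)
        ones = np.ones(len(blob))
        assert np.allclose(gnm.kirchhoff @ ones, 0.0)
        assert gnm.eigenvalues[0] == 0.0 and gnm.n_zero_modes == 1

    def test_eigenvalues_nonnegative(self, blob):
        gnm = gnm_modes(_ca_frame(blob), cutoff=6.0)
        assert np.all(gnm.eigenvalues >= 0)

    def test_disconnected_graph_warns_with_component_count(self):
        coords = np.vstack([np.eye(3), np.eye(3) + 100.0])
        with pytest.warns(UserWarning, match="2 components"):
            gnm = gnm_modes(_ca_frame(coords), cutoff=5.0)
        assert gnm.n_zero_modes == 2


def _dumbbell():
    """Two compact 8-residue domains bridged by one contact."""
    rng = np.random.default_rng(4)
    blob1 = rng.uniform(-2, 2, size=(7, 3))
    blob2 = rng.uniform(-2, 2, size=(7, 3)) + np.array([20.0, 0, 0])
    bridge1 = np.array([[7.0, 0, 0]])
    bridge2 = np.array([[13.0, 0, 0]])
    return _ca_frame(np.vstack([blob1, bridge1, bridge2, blob2]))


class TestHinges:
    def test_all_positive_mode_no_hinge(self):
        gnm = gnm_modes(_ca_frame(np.random.default_rng(0).uniform(-3, 3, (9, 3))), cutoff=20.0)
        # fully connected graph: fabricate the degenerate all-positive case
        gnm.eigenvectors[:, gnm.n_zero_modes] = np.abs(gnm.eigenvectors[:, gnm.n_zero_modes]) + 0.1
        assert detect_hinges(gnm) == []

    def test_dumbbell_single_hinge_at_linker(self):
        gnm = gnm_modes(_dumbbell(), cutoff=9.0)
        hinges = detect_hinges(gnm, min_segment=4)
        assert hinges == [(8, 9)]
        # independent check: slow mode splits the two domains by sign
        mode = gnm.slow_mode
        assert np.all(np.sign(mode[:8]) == np.sign(mode[0]))
        assert np.all(np.sign(mode[8:]) == -np.sign(mode[0]))

    def test_sign_flip_invariance(self):
        gnm = gnm_modes(_dumbbell(), cutoff=9.0)
        before = detect_hinges(gnm, min_segment=4)
        gnm.eigenvectors[:, gnm.n_zero_modes] *= -1.0
        assert detect_hinges(gnm, min_segment=4) == before

    def test_short_segments_suppressed(self):
        gnm = gnm_modes(_dumbbell(), cutoff=9.0)
        assert detect_hinges(gnm, min_segment=9) == []
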