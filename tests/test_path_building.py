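import numpy as np
import pytest

from pathmetad.errors import InputError
from pathmetad.geometry import rmsd
from pathmetad.path_building import (
    AbmdPool,
    DissimilarityMatrix,
    average_linkage,
    pairwise_rmsd,
    run_abmd,
    select_references,
)
from pathmetad.path_cv import compute_s, validate_path
from pathmetad.toy_systems import (
    TwoStateNetworkSystem,
    interpolated_trajectory,
    make_two_state_chain,
)

from conftest import random_conformation


def brute_force_average_linkage(dist):
    """O(n³) UPGMA with lexicographic tie-break: independent oracle."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, d, clusters[a] + clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def flat_clusters_from_merges(merges, n, k):
    """Cut the brute-force tree at k clusters; return a frame->set partition."""
    members = {i: frozenset([i]) for i in range(n)}
    next_id = n
    for a, b, _, merged in merges[: n - k]:
        members[next_id] = members.pop(a) | members.pop(b)
        next_id += 1
    return set(members.values())


def partition_from_labels(labels):
    out = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return set(frozenset(v) for v in out.values())


class TestPairwiseRmsd:
    def test_duplicates_give_zero(self, rng):
        c = random_conformation(rng, 8)
        mat = pairwise_rmsd([c, c, c])
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-7)

    def test_matches_per_pair_kernel(self, rng):
        frames = [random_conformation(rng, 8) for _ in range(5)]
        mat = pairwise_rmsd(frames)
        for i in range(5):
            for j in range(5):
                assert mat.values[i, j] == pytest.approx(
                    rmsd(frames[i], frames[j], fit=True), abs=1e-7
                )

    def test_triangle_inequality_spot_check(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 3, noise_sigma=0.0)
        mat = pairwise_rmsd(frames, mask=mini_receptor.ca_mask)
        d = mat.values
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-9

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InputError):
            DissimilarityMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestAverageLinkage:
    def test_two_frames_single_merge(self, rng):
        frames = [random_conformation(rng, 6) for _ in range(2)]
        mat = pairwise_rmsd(frames)
        tree = average_linkage(mat)
        assert tree.merges.shape[0] == 1
        assert tree.heights[0] == pytest.approx(mat.values[0, 1])

    def test_hand_traced_two_pair_layout(self):
        # two tight pairs 1 apart, 4 apart across: pairs merge first, then
        # the two pairs merge at the mean cross distance 4
        d = np.array([
            [0, 1, 4, 4],
            [1, 0, 4, 4],
            [4, 4, 0, 1],
            [4, 4, 1, 0],
        ], dtype=float)
        tree = average_linkage(DissimilarityMatrix(values=d))
        np.testing.assert_allclose(sorted(tree.heights), [1.0, 1.0, 4.0])
        labels = tree.cut(2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(50):
            n = 20
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = average_linkage(DissimilarityMatrix(values=d))
            merges = brute_force_average_linkage(d)
            for k in (2, 5, 9):
                expected = flat_clusters_from_merges(merges, n, k)
                got = partition_from_labels(tree.cut(k))
                assert got == expected, f"trial {trial}, cut {k}"

    def test_linkage_heights_monotone(self, rng):
        pts = rng.normal(size=(30, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = average_linkage(DissimilarityMatrix(values=d))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(18, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = average_linkage(DissimilarityMatrix(values=d))
        perm = rng.permutation(18)
        d2 = d[np.ix_(perm, perm)]
        tree2 = average_linkage(DissimilarityMatrix(values=d2))
        for k in (3, 7):
            p1 = partition_from_labels(tree.cut(k))
            p2 = {frozenset(int(perm[i]) for i in grp)
                  for grp in partition_from_labels(tree2.cut(k))}
            assert p1 == p2


class TestSelectReferences:
    def test_linear_interpolation_every_third_frame(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 30, noise_sigma=0.0)
        mat = pairwise_rmsd(frames, mask=mini_receptor.ca_mask)
        tree = average_linkage(mat)
        pset = select_references(
            tree, frames, k_cut=30, n_refs=10,
            endpoints=(frames[0], frames[-1]), mask=mini_receptor.ca_mask,
        )
        picked = [
            next(i for i, f in enumerate(frames)
                 if np.allclose(f.coords, r.coords))
            for r in pset.refs
        ]
        expected = np.round(np.linspace(0, 29, 10)).astype(int)
        assert picked[0] == 0 and picked[-1] == 29
        assert np.all(np.abs(np.array(picked) - expected) <= 1)
        s_vals = [compute_s(r, pset) for r in pset.refs]
        assert np.all(np.diff(s_vals) > 0)

    def test_selection_passes_path_validation(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 30, noise_sigma=0.0)
        mat = pairwise_rmsd(frames, mask=mini_receptor.ca_mask)
        tree = average_linkage(mat)
        pset = select_references(tree, frames, k_cut=30, n_refs=10,
                                 endpoints=(frames[0], frames[-1]),
                                 mask=mini_receptor.ca_mask)
        report = validate_path(pset)
        assert report.ok
        assert report.coefficient_of_variation < 0.5

    def test_two_references_are_endpoint_nearest_medoids(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 12, noise_sigma=0.0)
        mask = mini_receptor.ca_mask
        mat = pairwise_rmsd(frames, mask=mask)
        tree = average_linkage(mat)
        pset = select_references(tree, frames, k_cut=6, n_refs=2,
                                 endpoints=(frames[0], frames[-1]), mask=mask)
        # each reference is the medoid of the cluster nearest its endpoint:
        # closer to that endpoint than any other cluster's medoid could be
        span = rmsd(frames[0], frames[-1], mask=mask)
        assert rmsd(pset.refs[0], frames[0], mask=mask) < span / 6
        assert rmsd(pset.refs[1], frames[-1], mask=mask) < span / 6
        assert rmsd(pset.refs[0], frames[0], mask=mask) < rmsd(pset.refs[0], frames[-1], mask=mask)
        assert rmsd(pset.refs[1], frames[-1], mask=mask) < rmsd(pset.refs[1], frames[0], mask=mask)

    def test_invalid_counts_rejected(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 12, noise_sigma=0.0)
        mat = pairwise_rmsd(frames, mask=mini_receptor.ca_mask)
        tree = average_linkage(mat)
        with pytest.raises(InputError):
            select_references(tree, frames, k_cut=3, n_refs=5,
                              endpoints=(frames[0], frames[-1]))


class TestRunAbmd:
    @staticmethod
    def chain_system(**kw):
        inactive, active = make_two_state_chain(6, 5.0, seed=0)
        defaults = dict(barrier=0.75, asymmetry=-1.5, k_orth=100.0)
        defaults.update(kw)
        return TwoStateNetworkSystem(inactive, active, **defaults), active

    def test_zero_constant_reproduces_unbiased_dynamics(self):
        system, target = self.chain_system()
        kw = dict(n_runs=1, seed=9, steps=500, dt=0.001, stride=10,
                  integrator="baoab", friction=2.0)
        pool_biased = run_abmd(system, target, k=0.0, **kw)
        pool_plain = run_abmd(system, target, k=0.0, **kw)
        for a, b in zip(pool_biased.frames, pool_plain.frames):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_runs_reach_target(self):
        system, target = self.chain_system()
        pool = run_abmd(system, target, k=10.0, n_runs=3, seed=4, steps=20000,
                        dt=0.001, stride=50, integrator="baoab", friction=1.0)
        chi_init = pool.chi_series[0][0]
        for series in pool.chi_series:
            assert series.min() < 0.2 * chi_init

    def test_provenance_and_pool_shape(self):
        system, target = self.chain_system()
        pool = run_abmd(system, target, k=10.0, n_runs=2, seed=4, steps=400,
                        dt=0.001, stride=100, integrator="baoab", friction=2.0)
        assert isinstance(pool, AbmdPool)
        assert pool.n_frames == 2 * 4
        assert set(pool.provenance["run"]) == {0, 1}
        assert (pool.provenance["chi"] >= 0).all()
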