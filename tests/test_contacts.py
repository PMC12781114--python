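"""Contact kernel, occupancies, difference networks and communities."""

import numpy as np
import pytest

from nqogate import contacts as ct
from nqogate import trajectory as tj
from conftest import random_toy_structure


def _structure(coords, resids, elements=None, chains=None):
    n = len(coords)
    elements = elements or ["C"] * n
    chains = chains or ["A"] * n
    return tj.Structure(
        names=np.array([f"X{i}" for i in range(n)]),
        elements=np.array(elements), resids=np.array(resids, dtype=int),
        resnames=np.array(["GLY"] * n), chains=np.array(chains),
        xyz=np.array(coords, dtype=float))


def _pair_structure(distance, sep):
    """Two 1-atom residues a given distance apart and sequence gap."""
    return _structure([[0, 0, 0], [distance, 0, 0]], [1, 1 + sep])


class TestFrameContacts:
    def test_below_cutoff_is_contact(self):
        s = _pair_structure(4.4, 5)
        assert ct.frame_contacts(s.xyz, s) == {(0, 1)}

    def test_above_cutoff_is_not(self):
        s = _pair_structure(4.6, 5)
        assert ct.frame_contacts(s.xyz, s) == set()

    def test_boundary_distance_is_inclusive(self):
        s = _pair_structure(4.5, 5)
        assert ct.frame_contacts(s.xyz, s) == {(0, 1)}

    def test_sequence_separation_filter(self):
        s = _pair_structure(2.0, 2)
        assert ct.frame_contacts(s.xyz, s) == set()
        s3 = _pair_structure(2.0, 3)
        assert ct.frame_contacts(s3.xyz, s3) == {(0, 1)}

    def test_hydrogens_excluded(self):
        s = _structure([[0, 0, 0], [2.0, 0, 0], [50, 0, 0]],
                       [1, 5, 9], elements=["C", "H", "C"])
        assert ct.frame_contacts(s.xyz, s) == set()

    def test_cross_chain_pairs_ignore_sequence_separation(self):
        s = _structure([[0, 0, 0], [2.0, 0, 0]], [1, 2],
                       chains=["A", "B"])
        assert ct.frame_contacts(s.xyz, s) == {(0, 1)}

    @pytest.mark.parametrize("seed", range(6))
    def test_fast_kernel_equals_bruteforce_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy_structure(rng, n_residues=30)
        fast = ct.frame_contacts(s.xyz, s)
        brute = ct.frame_contacts_bruteforce(s.xyz, s)
        assert fast == brute


class TestContactProbabilities:
    def test_single_frame_values_are_binary(self, small_ensemble):
        _, top, traj, _ = small_ensemble
        one = tj.Trajectory(topology=top, xyz=traj.xyz[:1])
        m = ct.contact_probabilities(one)
        assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_scripted_duty_cycle(self):
        """Pair in contact 3 of 4 frames -> occupancy 0.75 exactly."""
        s = _pair_structure(3.0, 5)
        far = s.xyz.copy()
        far[1, 0] = 50.0
        traj = tj.Trajectory(topology=s,
                             xyz=np.stack([s.xyz, s.xyz, far, s.xyz]))
        m = ct.contact_probabilities(traj)
        assert m.values[0, 1] == pytest.approx(0.75)
        assert m.values[1, 0] == pytest.approx(0.75)
        assert m.n_frames_used == 4

    def test_probabilities_are_occupancies(self, small_ensemble):
        _, top, traj, _ = small_ensemble
        m = ct.contact_probabilities(
            tj.Trajectory(topology=top, xyz=traj.xyz[:30]))
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0
        np.testing.assert_allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)


def _matrix_from_pairs(n, pairs, labels=None):
    v = np.zeros((n, n))
    for (i, j), p in pairs.items():
        v[i, j] = v[j, i] = p
    labels = labels or tuple(("A", i + 1) for i in range(n))
    return ct.ContactProbabilityMatrix(values=v, residue_labels=labels,
                                       n_frames_used=10,
                                       min_sequence_separation=3)


class TestDifferenceNetwork:
    def test_identical_inputs_give_zero(self):
        m = _matrix_from_pairs(5, {(0, 3): 0.8})
        d = ct.difference_network(m, m)
        np.testing.assert_allclose(d.df, 0.0)

    def test_swapping_systems_negates_df(self):
        a = _matrix_from_pairs(5, {(0, 3): 0.9, (1, 4): 0.2})
        b = _matrix_from_pairs(5, {(0, 3): 0.1, (1, 4): 0.7})
        dab = ct.difference_network(a, b)
        dba = ct.difference_network(b, a)
        np.testing.assert_allclose(dab.df, -dba.df)

    def test_handcrafted_broken_contact(self):
        wt = _matrix_from_pairs(5, {(0, 4): 1.0})
        mut = _matrix_from_pairs(5, {(0, 4): 0.2})
        d = ct.difference_network(wt, mut)
        assert d.df[0, 4] == pytest.approx(-0.8)
        mask = np.ones((5, 5), bool)
        mask[0, 4] = mask[4, 0] = False
        np.testing.assert_allclose(d.df[mask], 0.0)

    def test_universe_mismatch_rejected(self):
        a = _matrix_from_pairs(5, {})
        b = _matrix_from_pairs(6, {})
        with pytest.raises(ValueError, match="universe"):
            ct.difference_network(a, b)


def _planted_two_cliques(p_intra=0.9, p_inter=0.1):
    """Two 6-residue cliques joined by one weak inter-clique pair."""
    pairs = {}
    for base in (0, 6):
        for i in range(6):
            for j in range(i + 1, 6):
                pairs[(base + i, base + j)] = p_intra
    pairs[(5, 6)] = p_inter
    return _matrix_from_pairs(12, pairs)


class TestCommunities:
    def test_planted_partition_recovered(self):
        m = _planted_two_cliques()
        part = ct.consensus_communities([m], stable_threshold=0.5)
        assert part.n_communities == 2
        assert len(set(part.labels[:6])) == 1
        assert len(set(part.labels[6:])) == 1
        assert part.labels[0] != part.labels[6]

    def test_single_clique_is_one_community(self):
        pairs = {(i, j): 0.95 for i in range(6) for j in range(i + 1, 6)}
        m = _matrix_from_pairs(6, pairs)
        part = ct.consensus_communities([m], stable_threshold=0.5)
        assert part.n_communities == 1

    def test_identical_blocks_are_idempotent_with_full_stability(self):
        m = _planted_two_cliques()
        single = ct.consensus_communities([m], stable_threshold=0.5)
        multi = ct.consensus_communities([m, m, m, m], stable_threshold=0.5)
        np.testing.assert_array_equal(single.labels, multi.labels)
        np.testing.assert_allclose(multi.stability, 1.0)

    def test_isolated_residue_is_flagged_singleton(self):
        m = _planted_two_cliques()
        v = np.zeros((13, 13))
        v[:12, :12] = m.values
        m13 = ct.ContactProbabilityMatrix(
            values=v, residue_labels=tuple(("A", i + 1) for i in range(13)),
            n_frames_used=10, min_sequence_separation=3)
        part = ct.consensus_communities([m13], stable_threshold=0.5)
        assert 12 in part.singletons
        assert np.sum(part.labels == part.labels[12]) == 1


class TestCommunityDifference:
    @pytest.fixture
    def partition(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        return ct.CommunityPartition(
            labels=labels, stability=np.ones(6),
            residue_labels=tuple(("A", i + 1) for i in range(6)))

    def _diff(self, pairs, n=6):
        v = np.zeros((n, n))
        for (i, j), d in pairs.items():
            v[i, j] = v[j, i] = d
        return ct.DifferenceNetwork(
            df=v, residue_labels=tuple(("A", i + 1) for i in range(n)),
            system_labels=("WT", "mut"))

    def test_all_zero_df_gives_zero_edges(self, partition):
        g = ct.community_difference(self._diff({}), partition)
        assert all(v == 0.0 for v in g.edges.values())
        assert g.total_df() == 0.0

    def test_interface_sums_signed_pairs(self, partition):
        g = ct.community_difference(
            self._diff({(0, 3): -0.5, (1, 4): -0.3, (2, 5): 0.1}), partition)
        assert g.edges[(1, 2)] == pytest.approx(-0.7)

    def test_conservation_over_interfaces_and_interiors(self, partition):
        rng = np.random.default_rng(0)
        pairs = {(i, j): rng.uniform(-1, 1)
                 for i in range(6) for j in range(i + 1, 6)}
        diff = self._diff(pairs)
        g = ct.community_difference(diff, partition)
        assert g.total_df() == pytest.approx(
            np.triu(diff.df, 1).sum(), abs=1e-9)

    def test_residue_permutation_leaves_sums_unchanged(self, partition):
        rng = np.random.default_rng(1)
        pairs = {(i, j): rng.uniform(-1, 1)
                 for i in range(6) for j in range(i + 1, 6)}
        diff = self._diff(pairs)
        g1 = ct.community_difference(diff, partition)
        perm = rng.permutation(6)
        v2 = diff.df[np.ix_(perm, perm)]
        diff2 = ct.DifferenceNetwork(
            df=v2, residue_labels=tuple(("A", int(p) + 1) for p in perm),
            system_labels=("WT", "mut"))
        part2 = ct.CommunityPartition(
            labels=partition.labels[perm], stability=np.ones(6),
            residue_labels=diff2.residue_labels)
        g2 = ct.community_difference(diff2, part2)
        assert g2.edges[(1, 2)] == pytest.approx(g1.edges[(1, 2)], abs=1e-12)


class TestSignificantEdges:
    def _diff(self, values):
        n = 5
        v = np.zeros((n, n))
        for (i, j), d in values.items():
            v[i, j] = v[j, i] = d
        return ct.DifferenceNetwork(
            df=v, residue_labels=tuple(("A", i + 1) for i in range(n)),
            system_labels=("WT", "mut"))

    def test_zero_threshold_returns_all_nonzero(self):
        d = self._diff({(0, 3): -0.8, (1, 4): 0.4, (0, 4): 0.5})
        assert len(ct.significant_edges(d, 0.0)) == 3

    def test_boundary_inclusive_default_half(self):
        d = self._diff({(0, 3): -0.8, (1, 4): 0.4, (0, 4): 0.5})
        edges = ct.significant_edges(d, 0.5)
        assert [e[0] for e in edges] == [(0, 3), (0, 4)]
        assert edges[0][1] == pytest.approx(-0.8)

    def test_sorted_by_magnitude_then_pair(self):
        d = self._diff({(0, 3): 0.6, (1, 4): -0.6, (0, 4): 0.9})
        edges = ct.significant_edges(d, 0.5)
        assert [e[0] for e in edges] == [(0, 4), (0, 3), (1, 4)]

    def test_system_swap_flips_signs_only(self):
        d = self._diff({(0, 3): -0.8, (1, 4): 0.6})
        flipped = ct.DifferenceNetwork(df=-d.df,
                                       residue_labels=d.residue_labels,
                                       system_labels=("mut", "WT"))
        e1 = ct.significant_edges(d, 0.5)
        e2 = ct.significant_edges(flipped, 0.5)
        assert [(p, -v) for p, v in e1] == e2
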