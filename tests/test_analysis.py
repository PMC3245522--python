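import itertools
import math

import numpy as np
import pytest

import chromosampler as cs
from chromosampler.analysis import ensemble_distance_matrix, label_agreement
from chromosampler.sampler import Ensemble

from conftest import rigid_motion


def make_ensemble(list_of_points, lps=None, chains=None):
    n = len(list_of_points)
    lps = lps if lps is not None else -np.arange(n, dtype=float)
    chains = chains if chains is not None else np.zeros(n, int)
    iters = np.concatenate([np.arange(np.sum(chains == c))
                            for c in np.unique(chains)])
    return Ensemble(np.stack(list_of_points), np.asarray(lps, float),
                    np.asarray(chains), iters)


def jitter_group(base, rng, n, scale):
    return [base + rng.standard_normal(base.shape) * scale for _ in range(n)]


class TestStructureDistance:
    def test_identity(self, rng):
        s = rng.standard_normal((6, 3))
        assert cs.structure_distance(s, s) == 0.0

    def test_mirror_zero(self, rng):
        s = rng.standard_normal((6, 3))
        mirror = s * np.array([1.0, 1.0, -1.0])
        assert cs.structure_distance(s, mirror) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_zero(self, rng):
        s = rng.standard_normal((6, 3))
        assert cs.structure_distance(s, rigid_motion(s, rng)) == \
            pytest.approx(0.0, abs=1e-8)

    def test_matches_double_loop(self, rng):
        s = rng.standard_normal((5, 3))
        t = rng.standard_normal((5, 3))
        total = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                ds = math.dist(s[i], s[j])
                dt = math.dist(t[i], t[j])
                total += (ds - dt) ** 2
        assert cs.structure_distance(s, t) == pytest.approx(math.sqrt(total),
                                                            rel=1e-12)

    def test_mismatched_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cs.structure_distance(rng.standard_normal((5, 3)),
                                  rng.standard_normal((6, 3)))

    def test_pseudometric_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = (rng.standard_normal((6, 3)) for _ in range(3))
            dab = cs.structure_distance(a, b)
            dbc = cs.structure_distance(b, c)
            dac = cs.structure_distance(a, c)
            assert dac <= dab + dbc + 1e-9
            assert dab == pytest.approx(cs.structure_distance(b, a))


class TestEnsembleDistanceMatrix:
    def test_identical_members_all_zero(self, rng):
        s = rng.standard_normal((5, 3))
        ens = make_ensemble([s, s.copy(), s.copy()])
        np.testing.assert_allclose(ensemble_distance_matrix(ens), 0.0)

    def test_entrywise_oracle(self, rng):
        members = [rng.standard_normal((5, 3)) for _ in range(3)]
        ens = make_ensemble(members)
        dm = ensemble_distance_matrix(ens)
        for i in range(3):
            for j in range(3):
                assert dm[i, j] == pytest.approx(
                    cs.structure_distance(members[i], members[j]), rel=1e-10)

    def test_permutation_consistency(self, rng):
        members = [rng.standard_normal((5, 3)) for _ in range(4)]
        dm = ensemble_distance_matrix(make_ensemble(members))
        perm = [2, 0, 3, 1]
        dmp = ensemble_distance_matrix(make_ensemble([members[p]
                                                      for p in perm]))
        np.testing.assert_allclose(dmp, dm[np.ix_(perm, perm)], rtol=1e-10)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_distance_matrix(make_ensemble([rng.standard_normal((4, 3))]))


class TestWardCluster:
    def test_two_group_recovery(self, rng):
        g1 = rng.standard_normal((8, 3))
        g2 = rng.standard_normal((8, 3)) * 25.0
        members = jitter_group(g1, rng, 10, 0.05) + \
            jitter_group(g2, rng, 14, 0.05)
        ens = make_ensemble(members)
        res = cs.ward_cluster(ensemble_distance_matrix(ens), 2)
        labels = res.labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        assert sorted(res.sizes.tolist()) == [10, 14]

    def test_degenerate_identical(self, rng):
        s = rng.standard_normal((5, 3))
        ens = make_ensemble([s.copy() for _ in range(6)])
        res = cs.ward_cluster(ensemble_distance_matrix(ens), 3)
        assert np.all(res.linkage[:, 2] == 0)
        assert len(res.labels) == 6

    def test_invalid_cluster_count(self, rng):
        ens = make_ensemble([rng.standard_normal((4, 3)) for _ in range(3)])
        dm = ensemble_distance_matrix(ens)
        with pytest.raises(ValueError):
            cs.ward_cluster(dm, 0)
        with pytest.raises(ValueError):
            cs.ward_cluster(dm, 4)


class TestKmeansCheck:
    def test_agrees_with_ward_on_separated_groups(self, rng):
        g1 = rng.standard_normal((8, 3))
        g2 = rng.standard_normal((8, 3)) * 25.0
        members = jitter_group(g1, rng, 12, 0.05) + \
            jitter_group(g2, rng, 12, 0.05)
        ens = make_ensemble(members)
        ward = cs.ward_cluster(ensemble_distance_matrix(ens), 2).labels
        km = cs.kmeans_check(ens, 2, seed=0)
        assert label_agreement(ward, km) == 1.0

    def test_self_agreement(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert label_agreement(labels, labels) == 1.0

    def test_agreement_invariant_to_relabeling(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([1, 1, 0, 0])
        assert label_agreement(a, b) == 1.0

    def test_seeded_determinism(self, rng):
        members = [rng.standard_normal((5, 3)) for _ in range(8)]
        ens = make_ensemble(members)
        np.testing.assert_array_equal(cs.kmeans_check(ens, 2, seed=3),
                                      cs.kmeans_check(ens, 2, seed=3))


class TestRepresentatives:
    def test_single_cluster(self, rng):
        members = [rng.standard_normal((4, 3)) for _ in range(5)]
        ens = make_ensemble(members, lps=[-9, -1, -5, -3, -7])
        reps = cs.representatives(ens, np.zeros(5, int))
        assert len(reps) == 1
        assert reps[0].index == 1
        assert reps[0].weight == 1.0

    def test_cluster_share_weights(self, rng):
        # 21 + 29 members -> weights 0.42 / 0.58
        members = [rng.standard_normal((4, 3)) for _ in range(50)]
        labels = np.array([0] * 21 + [1] * 29)
        reps = cs.representatives(make_ensemble(members), labels)
        weights = sorted(r.weight for r in reps)
        assert weights == [pytest.approx(0.42), pytest.approx(0.58)]
        assert sum(r.weight for r in reps) == pytest.approx(1.0)

    def test_argmax_matches_scan(self, rng):
        members = [rng.standard_normal((4, 3)) for _ in range(12)]
        lps = rng.standard_normal(12)
        labels = rng.integers(0, 3, 12)
        reps = cs.representatives(make_ensemble(members, lps=lps), labels)
        for r in reps:
            idx = [i for i in range(12) if labels[i] == r.label]
            best = max(idx, key=lambda i: lps[i])
            assert r.index == best

    def test_empty_labels_rejected(self, rng):
        ens = make_ensemble([rng.standard_normal((4, 3))])
        with pytest.raises(ValueError):
            cs.representatives(ens, [])


class TestReliableSubset:
    def test_identical_ensemble_tie_break(self, rng):
        s = rng.standard_normal((6, 3))
        ens = make_ensemble([s.copy() for _ in range(4)])
        res = cs.reliable_subset(ens, 3)
        assert sorted(res.fragments) == [0, 1, 2]
        assert res.score == 0.0

    def test_jittered_fragment_excluded(self, rng):
        base = rng.standard_normal((6, 3)) * 3
        members = []
        for _ in range(8):
            m = base.copy()
            m[2] += rng.standard_normal(3) * 2.0  # only fragment 2 moves
            members.append(m)
        for k in range(2, 6):
            res = cs.reliable_subset(make_ensemble(members), k)
            assert 2 not in res.fragments

    def test_greedy_vs_exhaustive(self, rng):
        from scipy.spatial.distance import squareform

        equal = 0
        for trial in range(10):
            members = [rng.standard_normal((7, 3)) for _ in range(6)]
            ens = make_ensemble(members)
            greedy = cs.reliable_subset(ens, 3)
            s = squareform(ens.distance_vectors().std(axis=0, ddof=0))

            def score(sub):
                return sum(s[a, b] for a, b in itertools.combinations(sub, 2))

            best = min(score(c) for c in itertools.combinations(range(7), 3))
            assert greedy.score >= best - 1e-12
            assert greedy.score == pytest.approx(score(greedy.fragments))
            if greedy.score <= best + 1e-12:
                equal += 1
        assert equal >= 1  # greedy is a heuristic but not hopeless

    def test_score_homogeneous_in_scale(self, rng):
        # scaling every member by c scales all distances, hence the score, by c
        members = [rng.standard_normal((6, 3)) * 3 for _ in range(5)]
        r1 = cs.reliable_subset(make_ensemble(members), 4)
        r2 = cs.reliable_subset(make_ensemble([0.25 * m for m in members]), 4)
        assert r2.score == pytest.approx(0.25 * r1.score, rel=1e-10)

    def test_score_shrinks_with_tightness(self, rng):
        # shrinking member-to-mean deviations shrinks s(i,j) ~ linearly
        base = rng.standard_normal((6, 3)) * 3
        devs = [rng.standard_normal(base.shape) * 0.1 for _ in range(5)]
        r1 = cs.reliable_subset(make_ensemble([base + d for d in devs]), 4)
        r2 = cs.reliable_subset(
            make_ensemble([base + 0.25 * d for d in devs]), 4)
        assert r2.score < r1.score
        assert r2.score == pytest.approx(0.25 * r1.score, rel=0.2)

    def test_k_out_of_range(self, rng):
        ens = make_ensemble([rng.standard_normal((5, 3)) for _ in range(3)])
        for k in (1, 6):
            with pytest.raises(ValueError):
                cs.reliable_subset(ens, k)


class TestSuperpose:
    def test_self_rmsd_zero(self, rng):
        s = rng.standard_normal((6, 3))
        _, rmsd = cs.superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self, rng):
        s = rng.standard_normal((6, 3))
        moved = rigid_motion(s, rng)
        aligned, rmsd = cs.superpose(moved, s)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(aligned.points, s, atol=1e-7)

    def test_mirror_needs_reflection_flag(self, rng):
        s = rng.standard_normal((6, 3))
        mirror = s * np.array([1.0, 1.0, -1.0])
        _, rmsd_no = cs.superpose(mirror, s, allow_reflection=False)
        _, rmsd_yes = cs.superpose(mirror, s, allow_reflection=True)
        assert rmsd_yes <= 1e-8
        assert rmsd_no > rmsd_yes

    def test_too_few_points(self, rng):
        s = rng.standard_normal((2, 3))
        with pytest.raises(ValueError):
            cs.superpose(s, s)


class TestGenomicDistanceProfile:
    def test_monotone_decay_on_straight_line(self, params):
        n = 12
        pts = np.column_stack([np.arange(n, dtype=float),
                               np.zeros(n), np.zeros(n)])
        fmap = cs.make_fragment_map(n, 1000)
        data = cs.simulate_5c(cs.Conformation(pts), fmap, params,
                              cs.NoiseSpec(mode="none"), even_odd_mask=False)
        edges = np.arange(500, 12_000, 1000)
        prof = cs.genomic_distance_profile(data, edges)
        vals = prof["mean_if"].dropna().to_numpy()
        assert np.all(np.diff(vals) < 0)

    def test_single_pair(self, params):
        fmap = cs.make_fragment_map(2, 1000)
        data = cs.InteractionDataset(fmap, "5C", [0], [1], [3.5], [0.1])
        prof = cs.genomic_distance_profile(data, [0, 2000])
        assert prof.loc[0, "mean_if"] == pytest.approx(3.5)
        assert prof.loc[0, "n_pairs"] == 1

    def test_empty_bins_missing(self, params):
        fmap = cs.make_fragment_map(2, 1000)
        data = cs.InteractionDataset(fmap, "5C", [0], [1], [3.5], [0.1])
        prof = cs.genomic_distance_profile(data, [10_000, 20_000, 30_000])
        assert prof["mean_if"].isna().all()
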