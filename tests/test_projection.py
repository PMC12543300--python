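import numpy as np
import pytest
from scipy import stats

from morphnet.projection import (
    RegionMatrix,
    aggregate_regions,
    matched_sparsity_hubs,
    presence_association,
    profile_cosine_correlation,
    similarity_by_projection_test,
    symmetrize,
    threshold_region_matrix,
)


def region_matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"r{i}" for i in range(values.shape[0])]
    return RegionMatrix(labels, values)


def random_symmetric(n, seed, low=0.1, high=1.0):
    rng = np.random.default_rng(seed)
    m = rng.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return region_matrix(m)


class TestAggregateRegions:
    def test_nonzero_mean_rule(self):
        # region A = {n0, n1}, region B = {n2}; values {0, 2, 4} across A-B
        values = np.zeros((3, 3))
        values[0, 2] = values[2, 0] = 0.0
        values[1, 2] = values[2, 1] = 2.0
        values[0, 1] = values[1, 0] = 4.0
        rm = aggregate_regions(values, ["n0", "n1", "n2"],
                               {"n0": "A", "n1": "A", "n2": "B"})
        assert rm.values[rm.labels.index("A"), rm.labels.index("B")] == 2.0
        assert rm.values[rm.labels.index("A"), rm.labels.index("A")] == 4.0

    def test_all_zero_pair_marks_absence(self):
        values = np.zeros((2, 2))
        rm = aggregate_regions(values, ["n0", "n1"], {"n0": "A", "n1": "B"})
        assert rm.values[0, 1] == 0.0

    def test_single_neuron_regions_pass_through(self):
        values = np.array([[0.0, 0.7], [0.7, 0.0]])
        rm = aggregate_regions(values, ["n0", "n1"], {"n0": "A", "n1": "B"})
        assert rm.values[0, 1] == pytest.approx(0.7)

    def test_neuron_order_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = [f"n{i}" for i in range(6)]
        regions = {l: ("A" if i % 2 else "B") for i, l in enumerate(labels)}
        rm1 = aggregate_regions(v, labels, regions)
        perm = rng.permutation(6)
        rm2 = aggregate_regions(v[np.ix_(perm, perm)],
                                [labels[i] for i in perm], regions)
        assert np.allclose(rm1.values, rm2.values)

    def test_unlabeled_neuron_rejected(self):
        with pytest.raises(ValueError, match="without region label"):
            aggregate_regions(np.zeros((2, 2)), ["n0", "n1"], {"n0": "A"})


class TestSymmetrize:
    def test_addition_with_transpose(self):
        rm = symmetrize(region_matrix([[0, 1], [2, 0]]))
        assert rm.values.tolist() == [[0, 3], [3, 0]]
        assert rm.symmetric

    def test_symmetric_input_doubles(self):
        m = random_symmetric(4, 2)
        out = symmetrize(m)
        assert np.allclose(out.values, 2 * m.values)

    def test_idempotent_up_to_scaling(self):
        m = region_matrix(np.arange(9.0).reshape(3, 3))
        once = symmetrize(m)
        twice = symmetrize(once)
        assert np.allclose(twice.values, 2 * once.values)


class TestPresenceAssociation:
    @staticmethod
    def matrices_from_table(a, b, c, d):
        """Region pair presence patterns hitting the 2x2 cells a..d times.

        The region count is the smallest with n(n-1)/2 >= a+b+c+d pairs;
        leftover pairs land in the absent/absent cell, so the *effective*
        table (a, b, c, d + leftover) is returned alongside.
        """
        n_pairs = a + b + c + d
        n = 2
        while n * (n - 1) // 2 < n_pairs:
            n += 1
        d += n * (n - 1) // 2 - n_pairs
        sim = np.zeros((n, n))
        proj = np.zeros((n, n))
        iu = np.stack(np.triu_indices(n, k=1), axis=1)[:n_pairs]
        flags = ([(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c)
        for (i, j), (s, p) in zip(iu, flags):
            sim[i, j] = sim[j, i] = 0.5 * s
            proj[i, j] = proj[j, i] = 0.8 * p
        return region_matrix(sim), region_matrix(proj), (a, b, c, d)

    def test_perfect_association(self):
        # 21 pairs split 10 present/present vs 11 absent/absent: phi = 1,
        # so the chi-square equals the pair count
        sim, proj, (a, b, c, d) = self.matrices_from_table(10, 0, 0, 10)
        chi2, p = presence_association(sim, proj)
        assert (a, b, c, d) == (10, 0, 0, 11)
        assert chi2 == pytest.approx(21.0)
        assert p < 1e-4

    def test_independence_gives_zero(self):
        # effective table [[1, 2], [6, 12]]: ad = bc
        sim, proj, (a, b, c, d) = self.matrices_from_table(1, 2, 6, 12)
        assert a * d == b * c
        chi2, _ = presence_association(sim, proj)
        assert chi2 == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        sim, proj, _ = self.matrices_from_table(10, 11, 0, 0)
        with pytest.raises(ValueError, match="degenerate"):
            presence_association(sim, proj)

    def test_matches_classic_two_by_two_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a0, b0, c0, d0 = (int(x) for x in rng.integers(1, 12, size=4))
            sim, proj, (a, b, c, d) = self.matrices_from_table(a0, b0, c0, d0)
            chi2, _ = presence_association(sim, proj)
            n = a + b + c + d
            want = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(float(want))


class TestSimilarityByProjection:
    def test_planted_difference_detected(self):
        rng = np.random.default_rng(4)
        n = 15
        proj = random_symmetric(n, 5)
        pv = proj.values.copy()
        pv[pv < np.quantile(pv[pv > 0], 0.5)] = 0.0
        proj = region_matrix(pv)
        sim = rng.normal(0, 0.1, (n, n))
        sim = (sim + sim.T) / 2
        sim[pv > 0] += 1.0  # projected pairs are one sd more similar
        res = similarity_by_projection_test(region_matrix(sim), proj,
                                            n=199, seed=6)
        assert res.p == pytest.approx(1 / 200)

    def test_calibrated_under_independence(self):
        rng = np.random.default_rng(7)
        rejections = 0
        trials = 200
        for t in range(trials):
            n = 12
            sim = rng.normal(size=(n, n))
            sim = (sim + sim.T) / 2
            proj = (rng.uniform(size=(n, n)) > 0.5).astype(float)
            proj = np.triu(proj, 1) + np.triu(proj, 1).T
            if proj.sum() == 0 or (proj == 0).all():
                continue
            try:
                res = similarity_by_projection_test(
                    region_matrix(sim), region_matrix(proj), n=99,
                    seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            rejections += res.p <= 0.05
        assert 0.02 <= rejections / trials <= 0.09

    def test_all_projected_rejected(self):
        sim = random_symmetric(5, 8)
        proj = random_symmetric(5, 9)
        with pytest.raises(ValueError, match="empty"):
            similarity_by_projection_test(sim, proj)


class TestProfileCosine:
    def test_identical_matrices_correlate_perfectly(self):
        m = random_symmetric(8, 10)
        assert profile_cosine_correlation(m, m) == pytest.approx(1.0)

    def test_orthogonal_profiles_score_zero(self):
        # regions 0 and 1 connect to disjoint partners ([1,0] vs [0,1]);
        # the 0-1 link itself is excluded as a mutual entry
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 1.0
        v[1, 3] = v[3, 1] = 1.0
        v[2, 3] = v[3, 2] = 0.5
        from morphnet.projection import _cosine_profile_matrix
        cm = _cosine_profile_matrix(region_matrix(v).values)
        assert cm[0, 1] == pytest.approx(0.0)
        assert cm[2, 3] == pytest.approx(0.0)

    def test_hand_built_four_region_oracle(self):
        sim = random_symmetric(4, 11)
        proj = random_symmetric(4, 12)
        got = profile_cosine_correlation(sim, proj)
        # independent re-computation
        def cosines(m):
            out = []
            for i in range(4):
                for j in range(i + 1, 4):
                    keep = [k for k in range(4) if k not in (i, j)]
                    u, v = m[i, keep], m[j, keep]
                    out.append(u @ v / np.linalg.norm(u) / np.linalg.norm(v))
            return np.array(out)
        want = stats.pearsonr(cosines(sim.values), cosines(proj.values))[0]
        assert got == pytest.approx(float(want))

    def test_zero_norm_profile_rejected(self):
        v = np.zeros((4, 4))
        v[2, 3] = v[3, 2] = 1.0
        with pytest.raises(ValueError, match="zero-norm"):
            profile_cosine_correlation(region_matrix(v), region_matrix(v))


class TestMatchedSparsityHubs:
    def test_identical_matrices_share_all_hubs(self):
        m = random_symmetric(20, 13)
        out = matched_sparsity_hubs(m, m, sparsity=0.3)
        assert out["degree_correlation"] == pytest.approx(1.0)
        assert out["common_hubs"] == sorted(out["hubs_similarity"].members)

    def test_published_edge_count_sparsity_round_trip(self):
        # 87 regions: 1,426 edges <-> printed sparsity 0.381,
        # 800 edges <-> printed sparsity 0.214
        m = random_symmetric(87, 14)
        out = matched_sparsity_hubs(m, m, n_edges=1426)
        assert out["n_edges"] == 1426
        assert round(out["sparsity"], 3) == 0.381
        net = threshold_region_matrix(m, n_edges=800)
        assert net.e == 800
        assert round(net.sparsity, 3) == 0.214

    def test_independent_matrices_decorrelate(self):
        rs = []
        for seed in range(6):
            a = random_symmetric(30, 100 + seed)
            b = random_symmetric(30, 200 + seed)
            rs.append(matched_sparsity_hubs(a, b, sparsity=0.25)
                      ["degree_correlation"])
        assert abs(np.mean(rs)) < 0.25

    def test_infeasible_sparsity_rejected(self):
        m = random_symmetric(10, 15)
        with pytest.raises(ValueError, match="infeasible"):
            threshold_region_matrix(m, n_edges=100)
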