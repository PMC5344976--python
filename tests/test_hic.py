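"""Contact-matrix operations: binning, pair classes, ICE, replicates, MMP."""

import warnings

import numpy as np
import pytest

import nucleoid3d as n3


def ice_oracle(values, tolerance=1e-5, max_iter=5000):
    """Independent brute-force iteration of the printed balancing update."""
    w = values.astype(float).copy()
    for _ in range(max_iter):
        r = w.sum(axis=1)
        total = r.sum()
        w = w * total / np.outer(r, r)
        r = w.sum(axis=1)
        if np.max(np.abs(r - r.mean())) / r.mean() < tolerance:
            break
    off = ~np.eye(w.shape[0], dtype=bool)
    return w / w[off].mean()


class TestBinContacts:
    def test_82_bins_for_the_816kb_genome_at_10kb(self):
        m = n3.bin_contacts([(0, 1, 1)], 816_394, 10_000)
        assert m.n_bins == 82

    def test_single_record_pools_symmetrically(self):
        m = n3.bin_contacts([(0, 15_000, 1)], 30_000, 10_000)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        np.testing.assert_array_equal(m.values, expected)

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        contacts = [(int(a), int(b), 1) for a, b in
                    rng.integers(0, 100_000, size=(1000, 2))]
        m = n3.bin_contacts(contacts, 100_000, 7000)
        assert np.triu(m.values).sum() == 1000
        assert m.total_reads == 1000

    def test_out_of_range_position_names_record(self):
        with pytest.raises(IndexError, match="record 1"):
            n3.bin_contacts([(0, 1, 1), (0, 99_999_999, 1)], 100_000, 10_000)


class TestClassifyPairs:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ((5, 5, "-", "+"), "self_ligation"),   # same-fragment circle, outward
            ((5, 5, "+", "+"), "self_ligation"),
            ((5, 5, "+", "-"), "non_ligation"),    # dangling end, inward
            ((3, 4, "+", "-"), "non_ligation"),    # adjacent inward
            ((4, 3, "-", "+"), "non_ligation"),    # adjacent inward, reversed record
            ((0, 19, "-", "+"), "non_ligation"),   # circularly adjacent inward
            ((3, 4, "-", "+"), "valid"),           # adjacent but outward
            ((2, 9, "+", "-"), "valid"),           # distant, any orientation
        ],
    )
    def test_rule_table(self, pair, expected):
        out = n3.classify_pairs([pair], n_fragments=20)
        assert out[expected] == [pair]

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(1)
        pairs = [(int(a), int(b), "+-"[s1], "+-"[s2])
                 for a, b, s1, s2 in zip(rng.integers(0, 50, 200), rng.integers(0, 50, 200),
                                         rng.integers(0, 2, 200), rng.integers(0, 2, 200))]
        out = n3.classify_pairs(pairs, n_fragments=50)
        assert sum(len(v) for v in out.values()) == 200

    def test_unknown_fragment_rejected(self):
        with pytest.raises(IndexError):
            n3.classify_pairs([(0, 99, "+", "-")], n_fragments=10)


class TestFilterWithControl:
    def make(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        v = rng.poisson(5.0, size=(n, n)).astype(float)
        v = np.triu(v) + np.triu(v, 1).T
        return n3.ContactMatrix(values=v, bin_size=1000)

    def test_empty_affected_set_is_identity(self):
        m, c = self.make(0), self.make(1)
        out = n3.filter_with_control(m, c, affected_bins=set())
        np.testing.assert_array_equal(out.values, m.values)
        assert out.state == "filtered"

    def test_supported_pair_is_zeroed_and_recorded(self):
        m, c = self.make(0), self.make(1)
        c.values[2, 5] = c.values[5, 2] = 1000.0  # clearly above any quantile
        out = n3.filter_with_control(m, c, affected_bins={2, 5})
        assert out.values[2, 5] == 0 and out.values[5, 2] == 0
        assert (2, 5) in out.removed_pairs
        assert out.removed_fraction > 0

    def test_never_increases_entries_and_keeps_near_diagonal(self):
        m, c = self.make(3), self.make(4)
        c.values[:] = 1000.0
        out = n3.filter_with_control(m, c, affected_bins=set(range(12)))
        assert np.all(out.values <= m.values)
        d = m.distance_matrix()
        np.testing.assert_array_equal(out.values[d <= 1], m.values[d <= 1])


class TestIceNormalize:
    @pytest.mark.parametrize("n,seed", [(10, 0), (25, 1), (50, 2)])
    def test_matches_brute_force_oracle_and_balances(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.poisson(8.0, size=(n, n)).astype(float) + 1.0
        v = np.triu(v) + np.triu(v, 1).T
        m = n3.ContactMatrix(values=v, bin_size=1000)
        out = n3.ice_normalize(m)
        r = out.values.sum(axis=1)
        assert np.max(np.abs(r - r.mean())) / r.mean() < 1e-5
        np.testing.assert_allclose(out.values, ice_oracle(v), atol=1e-9)

    def test_example_matrix_row_totals_balance(self):
        m = n3.ContactMatrix(values=[[0, 1, 2], [1, 0, 1], [2, 1, 0]], bin_size=1)
        out = n3.ice_normalize(m)
        r = out.values.sum(axis=1)
        assert np.max(np.abs(r - r.mean())) / r.mean() < 1e-5

    def test_constant_matrix_converges_in_one_cycle(self):
        m = n3.ContactMatrix(values=np.full((6, 6), 3.0), bin_size=1)
        out = n3.ice_normalize(m)
        assert out.n_ice_cycles == 1

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(5)
        v = rng.poisson(10.0, size=(15, 15)).astype(float) + 1.0
        v = np.triu(v) + np.triu(v, 1).T
        once = n3.ice_normalize(n3.ContactMatrix(values=v, bin_size=1000))
        twice = n3.ice_normalize(once)
        assert np.max(np.abs(twice.values - once.values)) <= 1e-4

    def test_zero_total_bin_auto_blacklisted_with_warning(self):
        v = np.ones((5, 5))
        v[2, :] = v[:, 2] = 0.0
        m = n3.ContactMatrix(values=v, bin_size=1000)
        with pytest.warns(UserWarning, match="blacklist"):
            out = n3.ice_normalize(m)
        assert 2 in out.blacklist
        with pytest.raises(ValueError):
            n3.ice_normalize(m, on_zero_total="error")

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(7)
        v = rng.poisson(5.0, size=(20, 20)).astype(float) + 1.0
        v = np.triu(v) + np.triu(v, 1).T
        out = n3.ice_normalize(n3.ContactMatrix(values=v, bin_size=1000))
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-9)


class TestSumReplicates:
    def test_single_matrix_scaled_by_its_total(self):
        v = np.array([[0.0, 2], [2, 0]])
        m = n3.ContactMatrix(values=v, bin_size=1)
        out = n3.sum_replicates([m])
        np.testing.assert_allclose(out.values, v / v.sum())

    def test_identical_replicates_keep_proportions(self):
        v = np.array([[0.0, 4, 2], [4, 0, 6], [2, 6, 0]])
        m = n3.ContactMatrix(values=v, bin_size=1)
        out = n3.sum_replicates([m, m])
        np.testing.assert_allclose(out.values / out.values.sum(), v / v.sum())

    def test_depth_imbalance_normalized_out(self):
        v = np.array([[0.0, 4, 2], [4, 0, 6], [2, 6, 0]])
        a = n3.ContactMatrix(values=v, bin_size=1)
        b = n3.ContactMatrix(values=10 * v, bin_size=1)
        out = n3.sum_replicates([a, b])
        np.testing.assert_allclose(out.values, 2 * v / v.sum())

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            n3.sum_replicates([])


class TestReplicateCorrelation:
    def test_identity_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(5.0, size=(10, 10)).astype(float)
        v = np.triu(v) + np.triu(v, 1).T
        a = n3.ContactMatrix(values=v, bin_size=1)
        b = n3.ContactMatrix(values=v.max() + 1 - v, bin_size=1)
        assert n3.replicate_correlation(a, a) == pytest.approx(1.0)
        assert n3.replicate_correlation(a, b) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = n3.ContactMatrix(values=np.ones((5, 5)), bin_size=1)
        b = n3.ContactMatrix(values=np.eye(5) + 1.0, bin_size=1)
        with pytest.raises(ValueError):
            n3.replicate_correlation(a, b)


class TestMmpScore:
    def structured_and_shuffled(self, seed):
        truth = n3.PlantedTruth(n_bins=60, true_borders=[0, 15, 30, 45],
                                decay_exponent=-1.0, domain_boost=3.0)
        raw = n3.simulate_contact_map(truth, 60, 50.0, seed=seed, bin_size=10_000)
        norm = n3.ice_normalize(raw)
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(60, 1)
        vals = norm.values[iu].copy()
        rng.shuffle(vals)
        shuf = np.zeros_like(norm.values)
        shuf[iu] = vals
        shuf = shuf + shuf.T
        np.fill_diagonal(shuf, np.diag(norm.values))
        return norm, n3.ContactMatrix(values=shuf, bin_size=10_000, state="normalized")

    def test_structured_scores_above_its_shuffle(self):
        diffs = []
        for seed in range(8):
            norm, shuf = self.structured_and_shuffled(seed)
            diffs.append(n3.mmp_score(norm, seed=seed).mmp_score
                         - n3.mmp_score(shuf, seed=seed).mmp_score)
        assert np.mean(diffs) > 0
        assert sum(d >= 0 for d in diffs) >= 6

    def test_score_in_unit_interval_with_finite_components(self):
        norm, _ = self.structured_and_shuffled(0)
        rep = n3.mmp_score(norm, seed=0)
        assert 0.0 < rep.mmp_score < 1.0
        for term in (rep.size_term, rep.eigenvector_term, rep.skewness_term,
                     rep.kurtosis_term):
            assert np.isfinite(term)

    def test_small_matrix_rejected(self):
        m = n3.ContactMatrix(values=np.ones((5, 5)), bin_size=1000, state="normalized")
        with pytest.raises(ValueError):
            n3.mmp_score(m)
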