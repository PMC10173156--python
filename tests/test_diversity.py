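import numpy as np
import pytest

from polycore.diversity import (
    DistanceMatrix,
    amova,
    fst_from_freqs,
    mrd_matrix,
    nei_fst,
    observed_heterozygosity,
)
from polycore.geno_io import MISSING, DosageMatrix, ValidationError

from .conftest import random_dosage_matrix


def _mat(rows, ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return DosageMatrix(ids, [f"m{j}" for j in range(rows.shape[1])], rows)


class TestHo:
    def test_all_heterozygous(self):
        assert observed_heterozygosity(_mat([[2, 2, 2]])).ho[0] == 1.0

    def test_all_homozygous(self):
        assert observed_heterozygosity(_mat([[0, 4, 0, 4]])).ho[0] == 0.0

    def test_direct_count(self):
        assert observed_heterozygosity(_mat([[0, 1, 2, 3, 4, 4]])).ho[0] == pytest.approx(0.5)

    def test_missing_excluded(self):
        m = _mat([[1, MISSING, 0, MISSING]])
        assert observed_heterozygosity(m).ho[0] == pytest.approx(0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError, match="s0"):
            observed_heterozygosity(_mat([[MISSING, MISSING]]))

    def test_group_means(self):
        m = _mat([[2, 2], [0, 0], [2, 0], [4, 4]])
        res = observed_heterozygosity(m, ["a", "a", "b", "b"])
        assert res.group_means["a"][0] == pytest.approx(0.5)
        assert res.group_means["b"][0] == pytest.approx(0.25)

    def test_binomial_tetraploid_matches_closed_form(self, rng):
        # dosage ~ Binomial(4, p): E[Ho] = 1 - p^4 - q^4
        p = 0.3
        calls = rng.binomial(4, p, size=(40, 4000)).astype(np.int8)
        m = _mat(calls)
        expected = 1 - p**4 - (1 - p) ** 4
        got = observed_heterozygosity(m).ho.mean()
        assert got == pytest.approx(expected, abs=0.01)


class TestMrd:
    def test_identity(self):
        m = _mat([[0, 1, 2], [0, 1, 2]])
        assert mrd_matrix(m).values[0, 1] == 0.0

    def test_maximal(self):
        m = _mat([[0, 0, 0], [4, 4, 4]])
        assert mrd_matrix(m).values[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        m = _mat([[0, 4], [4, 4]])
        assert mrd_matrix(m).values[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-5)

    def test_pairwise_complete_normalization(self):
        m = _mat([[0, MISSING], [4, 4]])
        # only one shared marker: d = |0 - 1| = 1
        assert mrd_matrix(m).values[0, 1] == pytest.approx(1.0)

    def test_no_shared_marker_errors(self):
        m = _mat([[0, MISSING], [MISSING, 4]])
        with pytest.raises(ValidationError, match="share no"):
            mrd_matrix(m)

    def test_brute_force_oracle(self, rng):
        m = random_dosage_matrix(rng, 10, 20, missing_rate=0.1)
        got = mrd_matrix(m).values
        p = m.calls.astype(float) / 4.0
        p[m.calls == MISSING] = np.nan
        for i in range(10):
            for j in range(10):
                shared = ~(np.isnan(p[i]) | np.isnan(p[j]))
                expect = np.sqrt(((p[i][shared] - p[j][shared]) ** 2).sum() / shared.sum())
                assert got[i, j] == pytest.approx(expect, abs=1e-12)

    def test_entries_in_unit_interval(self, rng):
        m = random_dosage_matrix(rng, 15, 30)
        v = mrd_matrix(m).values
        assert (v >= 0).all() and (v <= 1).all()


class TestFst:
    def test_identical_groups_zero(self):
        rows = [[0, 4, 2]] * 4
        m = _mat(rows)
        res = nei_fst(m, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert res.get("a", "b") == pytest.approx(0.0)

    def test_hand_example(self):
        # one informative locus: group freqs 0.2 vs 0.8
        # H_S = mean(0.32, 0.32) = 0.32, H_T = 0.5 -> FST = 0.36
        assert fst_from_freqs(np.array([[0.2], [0.8]])) == pytest.approx(0.36)
        ga = [[1], [1], [1], [1], [0]]  # sum 4 / 20 = 0.2
        gb = [[3], [3], [3], [3], [4]]  # 16 / 20 = 0.8
        m = _mat(ga + gb)
        res = nei_fst(m, ["a"] * 5 + ["b"] * 5, n_perm=9, seed=0)
        assert res.get("a", "b") == pytest.approx(0.36)

    def test_monomorphic_errors(self):
        m = _mat([[0, 0], [0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValidationError, match="monomorphic"):
            nei_fst(m, ["a", "a", "b", "b"], n_perm=9)

    def test_balding_nichols_matches_truth_oracle(self):
        from polycore.synthetic_data import SyntheticPanelConfig, simulate_panel

        cfg = SyntheticPanelConfig(
            group_sizes=(60, 60),
            group_ploidy=(4, 4),
            n_markers=2000,
            divergence=0.3,
            seed=11,
        )
        matrix, _, truth = simulate_panel(cfg)
        labels = [f"g{k}" for k in truth.labels]
        res = nei_fst(matrix, labels, n_perm=9, seed=0)
        oracle = fst_from_freqs(truth.group_freqs)
        assert res.get("g0", "g1") == pytest.approx(oracle, abs=0.05)

    def test_permutation_seed_reproducible(self, rng):
        m = random_dosage_matrix(rng, 16, 30)
        labels = ["a"] * 8 + ["b"] * 8
        r1 = nei_fst(m, labels, n_perm=49, seed=3)
        r2 = nei_fst(m, labels, n_perm=49, seed=3)
        assert r1.p_values == r2.p_values


def _points_dist(x, ids=None):
    x = np.asarray(x, dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(ids or [f"s{i}" for i in range(len(x))], d, "MRD")


class TestAmova:
    def test_perfect_separation(self):
        d = np.ones((4, 4))
        d[np.ix_([0, 1], [0, 1])] = 0.0
        d[np.ix_([2, 3], [2, 3])] = 0.0
        dist = DistanceMatrix(["a", "b", "c", "d"], d, "MRD")
        res = amova(dist, ["g1", "g1", "g2", "g2"], n_perm=9, seed=0)
        assert res.phi == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_hand_computed_toy(self):
        # points [0,1,2] vs [10,11,12]: SS_total = 154, SS_within = 4,
        # n0 = 3, sigma2 = (49.667, 1) -> Phi = 149/152
        dist = _points_dist([0, 1, 2, 10, 11, 12])
        res = amova(dist, ["a", "a", "a", "b", "b", "b"], n_perm=99, seed=0)
        assert res.phi == pytest.approx(149 / 152, abs=1e-12)
        assert res.sigma2_within == pytest.approx(1.0)
        assert res.sigma2_among == pytest.approx(149 / 3)
        # only 10 distinct 3|3 splits exist, so p can be no smaller than ~0.1
        assert res.p_value <= 0.2

    def test_percentages_sum_to_100(self, rng):
        x = rng.normal(size=12)
        dist = _points_dist(x)
        labels = ["a"] * 6 + ["b"] * 6
        res = amova(dist, labels, n_perm=19, seed=1)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-12)

    def test_null_phi_near_zero(self, rng):
        n_ok = 0
        for rep in range(20):
            x = rng.normal(size=20)
            dist = _points_dist(x)
            labels = list(rng.permutation(["a"] * 10 + ["b"] * 10))
            res = amova(dist, labels, n_perm=99, seed=rep)
            if res.p_value > 0.05:
                n_ok += 1
            assert res.phi < 0.5
        assert n_ok >= 19

    def test_p_floor(self):
        dist = _points_dist([0, 0.1, 0.2, 10, 10.1, 10.2])
        res = amova(dist, ["a", "a", "a", "b", "b", "b"], n_perm=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_reorder_invariance(self, rng):
        x = rng.normal(size=10)
        labels = ["a"] * 5 + ["b"] * 5
        dist = _points_dist(x)
        perm = rng.permutation(10)
        dist2 = DistanceMatrix(
            [dist.ids[i] for i in perm], dist.values[np.ix_(perm, perm)], "MRD"
        )
        labels2 = [labels[i] for i in perm]
        r1 = amova(dist, labels, n_perm=0, seed=0)
        r2 = amova(dist2, labels2, n_perm=0, seed=0)
        assert r1.phi == pytest.approx(r2.phi, abs=1e-12)

    def test_singleton_group_errors(self):
        dist = _points_dist([0, 1, 2])
        with pytest.raises(ValidationError):
            amova(dist, ["a", "a", "b"], n_perm=9)
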