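import numpy as np
import pandas as pd
import pytest

from sandpop.genotype_io import MISSING, GenotypeMatrix
from sandpop.differentiation import (
    amova_three_level,
    great_circle_matrix,
    mantel_test,
    multilocus_theta,
    nei_ds,
    pairwise_wc_fst,
)
from sandpop.synthetic_data import IslandModelSpec, simulate_island_model


def _two_pop(calls_a, calls_b):
    a = np.asarray(calls_a, dtype=np.int16)
    b = np.asarray(calls_b, dtype=np.int16)
    calls = np.vstack([a, b])
    return GenotypeMatrix(
        [f"i{k}" for k in range(calls.shape[0])],
        ["A"] * a.shape[0] + ["B"] * b.shape[0],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
    )


class TestPairwiseFst:
    def test_fixed_differences_give_theta_one(self):
        m = _two_pop(np.zeros((5, 10)), np.full((10, 10), 2))
        theta, _ = pairwise_wc_fst(m, "A", "B", n_perm=0)
        assert theta == pytest.approx(1.0)

    def test_duplicated_population_gives_no_structure(self):
        rng = np.random.default_rng(3)
        block = rng.binomial(2, 0.4, size=(30, 500))
        half = np.vstack([block, block])
        rng.shuffle(half)
        m = _two_pop(half[:30], half[30:])
        theta, p = pairwise_wc_fst(m, "A", "B", n_perm=199, seed=1)
        assert abs(theta) < 0.01
        assert p > 0.05

    def test_permutation_p_small_under_structure(self):
        m = simulate_island_model(
            IslandModelSpec(n_pops=2, n_per_pop=(20, 20), n_loci=300, fst=0.1, seed=6))
        theta, p = pairwise_wc_fst(m, *m.pop_labels, n_perm=199, seed=1)
        assert theta > 0.05
        assert p == pytest.approx(1 / 200)

    def test_balding_nichols_recovery_smallscale(self):
        m = simulate_island_model(
            IslandModelSpec(n_pops=6, n_per_pop=(40,) * 6, n_loci=1500, fst=0.05, seed=12))
        groups = list(m.pop_indices().values())
        theta = multilocus_theta(m.calls, groups)
        assert theta == pytest.approx(0.05, abs=0.01)

    def test_all_monomorphic_is_undefined(self):
        m = _two_pop(np.zeros((3, 4)), np.zeros((3, 4)))
        with pytest.raises(ValueError):
            pairwise_wc_fst(m, "A", "B", n_perm=0)


class TestNeiDs:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(7)
        block = rng.binomial(2, 0.5, size=(200, 400))
        m = _two_pop(block[:100], block[100:])
        assert nei_ds(m, "A", "B") < 0.005

    def test_fixed_opposite_alleles_infinite(self):
        m = _two_pop(np.zeros((5, 6)), np.full((5, 6), 2))
        assert nei_ds(m, "A", "B") == np.inf

    def test_ranks_concordant_with_theta(self):
        m = simulate_island_model(IslandModelSpec(
            n_pops=3, n_per_pop=(30, 30, 30), n_loci=800,
            fst=0.02, fst_per_pop=(0.02, 0.02, 0.15), seed=8))
        pops = m.pop_labels
        th_near, _ = pairwise_wc_fst(m, pops[0], pops[1], n_perm=0)
        th_far, _ = pairwise_wc_fst(m, pops[0], pops[2], n_perm=0)
        assert th_far > th_near
        assert nei_ds(m, pops[0], pops[2]) > nei_ds(m, pops[0], pops[1])


def _amova_oracle(matrix):
    """Plain-loop allele-level AMOVA components, independent of the
    vectorised implementation."""
    pops = matrix.pop_indices()
    s_ap = s_ai = s_wi = 0.0
    for j in range(matrix.n_loci):
        ss_ap = ss_ai = ss_wi = 0.0
        all_means, pop_of = [], []
        pop_means = {}
        for pop, idx in pops.items():
            vals = [matrix.calls[i, j] for i in idx if matrix.calls[i, j] != MISSING]
            if vals:
                pop_means[pop] = np.mean([v / 2 for v in vals])
        total_alleles, total_sum = 0, 0.0
        for pop, idx in pops.items():
            for i in idx:
                d = matrix.calls[i, j]
                if d == MISSING:
                    continue
                total_alleles += 2
                total_sum += d
        if total_alleles == 0:
            continue
        grand = total_sum / total_alleles
        Ns = {}
        for pop, idx in pops.items():
            n_typed = 0
            for i in idx:
                d = matrix.calls[i, j]
                if d == MISSING:
                    continue
                n_typed += 1
                ind_mean = d / 2
                for allele in ([1, 1] if d == 2 else [1, 0] if d == 1 else [0, 0]):
                    ss_wi += (allele - ind_mean) ** 2
                ss_ai += 2 * (ind_mean - pop_means[pop]) ** 2
            if n_typed:
                Ns[pop] = n_typed
                ss_ap += 2 * n_typed * (pop_means[pop] - grand) ** 2
        r = len(Ns)
        N = sum(Ns.values())
        if r < 2 or N - r <= 0:
            continue
        ms_ap = ss_ap / (r - 1)
        ms_ai = ss_ai / (N - r)
        ms_wi = ss_wi / N
        nc = (N - sum(v**2 for v in Ns.values()) / N) / (r - 1)
        s_wi += ms_wi
        s_ai += (ms_ai - ms_wi) / 2
        s_ap += (ms_ap - ms_ai) / (2 * nc)
    return s_ap, s_ai, s_wi


class TestAMOVA:
    def test_matches_plain_loop_oracle(self, island_matrix):
        res = amova_three_level(island_matrix, n_perm=0)
        oracle = _amova_oracle(island_matrix)
        got = [res.components[k] for k in
               ("among_populations", "among_individuals", "within_individuals")]
        np.testing.assert_allclose(got, oracle, rtol=1e-9)

    def test_percentages_sum_to_100(self, island_matrix):
        res = amova_three_level(island_matrix, n_perm=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.1)

    def test_identical_homozygotes_undefined(self):
        m = _two_pop(np.zeros((3, 5)), np.zeros((3, 5)))
        with pytest.raises(ValueError):
            amova_three_level(m, n_perm=0)

    def test_singleton_population_rejected(self):
        m = _two_pop(np.zeros((1, 5)), np.array([[0, 1, 2, 1, 0]] * 3))
        with pytest.raises(ValueError):
            amova_three_level(m, n_perm=0)

    def test_panmictic_vs_structured_p_values(self):
        rng = np.random.default_rng(10)
        pan = rng.binomial(2, 0.4, size=(60, 300)).astype(np.int16)
        m_pan = _two_pop(pan[:30], pan[30:])
        res_pan = amova_three_level(m_pan, n_perm=99, seed=1)
        assert res_pan.p_values["among_populations"] > 0.05
        m_str = simulate_island_model(
            IslandModelSpec(n_pops=2, n_per_pop=(30, 30), n_loci=300, fst=0.08, seed=13))
        res_str = amova_three_level(m_str, n_perm=99, seed=1)
        assert res_str.p_values["among_populations"] < 0.05
        assert res_str.percentages["among_populations"] > res_pan.percentages["among_populations"]


class TestMantel:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 5))
        A = (x + x.T) / 2
        np.fill_diagonal(A, 0)
        r, _ = mantel_test(A, A.copy(), n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        r2, _ = mantel_test(A, 10.0 - A, n_perm=99, seed=0)
        np.fill_diagonal(A, 0)
        assert r2 == pytest.approx(-1.0)

    def test_matches_hand_pearson_on_toy(self):
        A = np.array([
            [0, 1, 2, 3],
            [1, 0, 4, 5],
            [2, 4, 0, 6],
            [3, 5, 6, 0.0],
        ])
        B = np.array([
            [0, 2, 1, 7],
            [2, 0, 3, 2],
            [1, 3, 0, 4],
            [7, 2, 4, 0.0],
        ])
        va = [1, 2, 3, 4, 5, 6]
        vb = [2, 1, 7, 3, 2, 4]
        r, _ = mantel_test(A, B, n_perm=9, seed=0)
        assert r == pytest.approx(np.corrcoef(va, vb)[0, 1])

    def test_constant_matrix_rejected(self):
        A = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            mantel_test(A, A * 0.0, n_perm=9)


class TestGreatCircle:
    def _sites(self, coords):
        return pd.DataFrame(
            [{"population": f"s{k}", "latitude": la, "longitude": lo}
             for k, (la, lo) in enumerate(coords)])

    def test_identical_and_antipodal_points(self):
        d = great_circle_matrix(self._sites([(10, 20), (10, 20), (-10, -160)]))
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(np.pi * 6371, rel=1e-6)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        coords = [(la, lo) for la, lo in zip(rng.uniform(-80, 80, 6), rng.uniform(-170, 170, 6))]
        d = great_circle_matrix(self._sites(coords)).to_numpy()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6
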