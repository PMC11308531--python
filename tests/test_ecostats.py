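"""Bray-Curtis, Mantel, PERMANOVA, rank tests and nMDS against oracles.

Where scikit-bio implements the same statistic it serves as an
independent cross-check of the implementation here.
"""

import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as skbd
from scipy import stats as sps
from skbio import DistanceMatrix

from mermine.ecostats import (
    bray_curtis,
    euclidean_env,
    kruskal_wallis,
    mantel,
    nmds,
    pairwise_wilcoxon,
    permanova,
    permanova_covariates,
)
from mermine.seqio import CountMatrix, SampleMetadata

from _oracles import (
    anderson_pseudo_f,
    exhaustive_mantel_p,
    exhaustive_permanova_p,
)


def _cm(matrix, samples=None, genes=None) -> CountMatrix:
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{i}" for i in range(matrix.shape[1])]
    return CountMatrix(data=pd.DataFrame(matrix, index=genes, columns=samples))


def _random_dm(rng, n) -> DistanceMatrix:
    x = rng.random((n, 3))
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(n)])


class TestBrayCurtis:
    def test_identical_samples_have_zero_dissimilarity(self):
        d = bray_curtis(_cm([[3, 3], [1, 1]]))
        assert d[0, 1] == 0.0

    def test_disjoint_supports_give_one(self):
        d = bray_curtis(_cm([[5, 0], [0, 7]]))
        assert d[0, 1] == 1.0

    def test_hand_computed_example(self):
        d = bray_curtis(_cm([[1, 3], [2, 2], [3, 1]]))
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            bray_curtis(_cm([[1, 0], [1, 0]]))

    def test_bounds_symmetry_zero_diagonal(self, rng):
        for _ in range(5):
            m = rng.integers(0, 50, size=(8, 6)).astype(float)
            m[0] += 1  # no all-zero sample
            d = bray_curtis(_cm(m))
            a = d.data
            assert (a >= 0).all() and (a <= 1).all()
            np.testing.assert_allclose(a, a.T)
            assert np.all(np.diag(a) == 0)


class TestEuclideanEnv:
    def test_standardized_distance(self):
        meta = SampleMetadata(data=pd.DataFrame(
            {"AOU": [0.0, 2.0], "salinity": [1.0, 3.0]}, index=["s1", "s2"]))
        d = euclidean_env(meta)
        # both covariates standardize to (-1, 1): distance = sqrt(4 + 4)
        assert d[0, 1] == pytest.approx(np.sqrt(8.0))

    def test_missing_values_pairwise_complete(self):
        meta = SampleMetadata(data=pd.DataFrame(
            {"a": [0.0, 1.0, 2.0], "b": [0.0, np.nan, 2.0]},
            index=["s1", "s2", "s3"]))
        d = euclidean_env(meta, standardize=False)
        # s1-s2 share only covariate a; squared distance rescaled 2/1
        assert d[0, 1] == pytest.approx(np.sqrt(1.0 * 2))
        assert d[0, 2] == pytest.approx(np.sqrt(8.0))


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        d = _random_dm(rng, 6)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration_at_n4(self, rng):
        d1, d2 = _random_dm(rng, 4), _random_dm(rng, 4)
        res = mantel(d1, d2, n_perm=999, method="exact")
        r_want, p_want = exhaustive_mantel_p(d1.data, d2.data)
        assert res.method == "exact" and res.n_permutations == 24
        assert res.statistic == pytest.approx(r_want)
        assert res.p_value == pytest.approx(p_want)

    def test_statistic_agrees_with_scikit_bio(self, rng):
        d1, d2 = _random_dm(rng, 10), _random_dm(rng, 10)
        res = mantel(d1, d2, n_perm=99, seed=1)
        r_skbio, _, _ = skbd.mantel(d1, d2, permutations=0)
        assert res.statistic == pytest.approx(float(r_skbio))

    def test_too_few_samples_rejected(self, rng):
        d = _random_dm(rng, 3)
        with pytest.raises(ValueError):
            mantel(d, d)

    def test_p_respects_permutation_floor_and_reproducibility(self, rng):
        d1, d2 = _random_dm(rng, 8), _random_dm(rng, 8)
        r1 = mantel(d1, d2, n_perm=99, seed=7)
        r2 = mantel(d1, d2, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value >= 1 / 100

    def test_null_p_values_near_uniform(self):
        """Independent random matrices: permutation p-values over 200
        replicates stay within Kolmogorov distance 0.1 of uniform."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            d1, d2 = _random_dm(rng, 6), _random_dm(rng, 6)
            ps.append(mantel(d1, d2, n_perm=99,
                             seed=int(rng.integers(2**31))).p_value)
        grid = np.sort(ps)
        ks = np.max(np.abs(grid - (np.arange(1, 201)) / 200))
        assert ks < 0.1


class TestPermanova:
    def test_single_group_rejected(self, rng):
        d = _random_dm(rng, 6)
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 6)

    def test_group_of_size_one_rejected(self, rng):
        d = _random_dm(rng, 5)
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a", "b"])

    def test_exact_f_and_p_match_brute_force(self, rng):
        d = _random_dm(rng, 6)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, n_perm=999, method="exact")
        f_want, p_want = exhaustive_permanova_p(d.data, labels)
        assert res.method == "exact" and res.n_permutations == 20
        assert res.statistic == pytest.approx(f_want)
        assert res.p_value == pytest.approx(p_want)

    def test_pseudo_f_agrees_with_scikit_bio(self, rng):
        d = _random_dm(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(d, labels, n_perm=99, seed=2)
        sk = skbd.permanova(d, grouping=labels, permutations=0)
        assert res.statistic == pytest.approx(float(sk["test statistic"]))
        assert res.statistic == pytest.approx(anderson_pseudo_f(d.data, labels))

    def test_type_one_error_calibrated(self):
        """Null labels: rejection rate at alpha=0.05 stays within
        0.05 +/- 0.03 over 200 simulations."""
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(200):
            d = _random_dm(rng, 12)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            res = permanova(d, labels, n_perm=199,
                            seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert abs(rejections / 200 - 0.05) <= 0.03

    def test_distance_regression_detects_gradient(self, rng):
        n = 14
        grad = np.linspace(0, 1, n)
        x = np.column_stack([grad, rng.random(n)])
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(x)),
                           ids=[f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"grad": grad}, index=list(d.ids))
        res = permanova_covariates(d, cov, n_perm=199, seed=4)
        assert res.p_value <= 0.01


class TestRankTests:
    def test_identical_group_multisets_give_h_zero(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        h, p = kruskal_wallis(values, groups)
        assert h == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_ranked_computation(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6],
                              ["a", "a", "a", "b", "b", "b"])
        # ranks 1..6, R_a = 6, R_b = 15: H = 12/42 * (12 + 75) - 21
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        h_sp, p_sp = sps.kruskal([1, 2, 3], [4, 5, 6])
        assert (h, p) == (pytest.approx(h_sp), pytest.approx(p_sp))

    def test_constant_values_return_h0_p1_not_error(self):
        h, p = kruskal_wallis([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert (h, p) == (0.0, 1.0)

    def test_holm_corrected_p_monotone(self, rng):
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8),
                                 rng.normal(4, 1, 8)])
        groups = np.repeat(["a", "b", "c"], 8)
        pm = pairwise_wilcoxon(values, groups, correction="holm")
        raw = pairwise_wilcoxon(values, groups, correction="holm")
        assert pm.loc["a", "b"] == raw.loc["b", "a"]  # symmetric
        ps = [pm.loc["a", "b"], pm.loc["a", "c"], pm.loc["b", "c"]]
        assert all(0 < p <= 1 for p in ps)
        # Holm never reports smaller than the raw Mann-Whitney p
        for g1, g2 in [("a", "b"), ("a", "c"), ("b", "c")]:
            _, p_raw = sps.mannwhitneyu(values[groups == g1],
                                        values[groups == g2],
                                        alternative="two-sided")
            assert pm.loc[g1, g2] >= p_raw - 1e-12


class TestNmds:
    def test_planar_configuration_recovered(self, rng):
        x = rng.random((10, 2))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(x)),
                           ids=[f"s{i}" for i in range(10)])
        res = nmds(d, k=2, n_starts=2, seed=0)
        assert res.stress < 0.01

    def test_stress_history_non_increasing(self, rng):
        d = _random_dm(rng, 9)
        res = nmds(d, k=2, n_starts=1, seed=1)
        h = res.stress_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_stress_invariant_under_sample_reordering(self, rng):
        d = _random_dm(rng, 8)
        perm = list(rng.permutation(list(d.ids)))
        res1 = nmds(d, k=2, n_starts=1, seed=2)
        res2 = nmds(d.filter(perm), k=2, n_starts=1, seed=2)
        assert res1.stress == pytest.approx(res2.stress, abs=1e-6)

    def test_k_must_be_below_n(self, rng):
        d = _random_dm(rng, 4)
        with pytest.raises(ValueError):
            nmds(d, k=4)
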