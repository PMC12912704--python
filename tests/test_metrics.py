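import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stimpute.core_data import ExpressionMatrix
from stimpute.metrics import (
    ami,
    ari,
    as_score,
    cluster_cells,
    homo,
    js_gene,
    js_histogram,
    nmi,
    rmse_gene,
    spcc_gene,
    ssim_gene,
)


class TestSpearman:
    def test_identity_and_reversal(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spcc_gene(v, v) == pytest.approx(1.0)
        order = np.argsort(v)
        rev = np.empty_like(v)
        rev[order] = v[order[::-1]]
        assert spcc_gene(rev, v) == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        pred = rng.normal(size=5)
        truth = rng.normal(size=5)
        rp = np.argsort(np.argsort(pred)).astype(float)
        rt = np.argsort(np.argsort(truth)).astype(float)
        oracle = np.corrcoef(rp, rt)[0, 1]
        assert abs(spcc_gene(pred, truth) - oracle) <= 1e-12

    def test_classic_d2_formula_on_tiefree_data(self, rng):
        pred = rng.permutation(8).astype(float)
        truth = rng.permutation(8).astype(float)
        rp = np.argsort(np.argsort(pred)) + 1
        rt = np.argsort(np.argsort(truth)) + 1
        n = 8
        oracle = 1 - 6 * np.sum((rp - rt) ** 2) / (n * (n ** 2 - 1))
        assert abs(spcc_gene(pred, truth) - oracle) <= 1e-12

    def test_monotone_transform_invariance(self, rng):
        pred = rng.normal(size=20)
        truth = rng.normal(size=20)
        assert spcc_gene(np.exp(pred), truth) == pytest.approx(
            spcc_gene(pred, truth))

    def test_constant_vector_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(spcc_gene(np.ones(5), np.arange(5.0)))


class TestSSIM:
    def test_perfect_prediction(self, rng):
        v = rng.random(10)
        assert ssim_gene(v, v) == pytest.approx(1.0)

    def test_mismatched_constants_score_low(self):
        assert ssim_gene(np.zeros(6), np.ones(6)) < 0.1

    def test_symmetric(self, rng):
        a, b = rng.random(8), rng.random(8)
        assert ssim_gene(a, b) == pytest.approx(ssim_gene(b, a))

    def test_closed_form_small_instance(self):
        t = np.array([0.0, 0.5, 1.0])
        p = np.array([0.0, 1.0, 0.5])
        c1, c2 = 0.01, 0.03
        mu_t, mu_p = t.mean(), p.mean()
        cov = ((t - mu_t) * (p - mu_p)).mean()
        num = (2 * mu_t * mu_p + c1**2) * (2 * cov + c2**2)
        den = (mu_t**2 + mu_p**2 + c1**2) * (t.var() + p.var() + c2**2)
        assert ssim_gene(p, t) == pytest.approx(num / den, abs=1e-12)


class TestRMSE:
    def test_perfect_prediction(self, rng):
        v = rng.normal(size=7)
        assert rmse_gene(v, v) == pytest.approx(0.0)

    def test_hand_zscored_three_vector(self):
        p = np.array([1.0, 2.0, 3.0])
        t = np.array([2.0, 2.0, 5.0])
        zp = (p - p.mean()) / p.std()
        zt = (t - t.mean()) / t.std()
        expected = np.sqrt(np.mean((zp - zt) ** 2))
        assert rmse_gene(p, t) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        p, t = rng.normal(size=9), rng.normal(size=9)
        assert rmse_gene(3 * p + 2, 3 * t + 2) == pytest.approx(
            rmse_gene(p, t))

    def test_zero_variance_fallback_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = rmse_gene(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))
        assert out == pytest.approx(np.sqrt(np.mean((1 - np.arange(1.0, 5)) ** 2)))


class TestJS:
    def test_proportional_is_zero(self):
        assert js_gene(np.array([2.0, 4.0, 6.0]),
                       np.array([1.0, 2.0, 3.0])) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_ln2(self):
        assert js_gene(np.array([1.0, 0.0]),
                       np.array([0.0, 1.0])) == pytest.approx(np.log(2), abs=1e-10)

    def test_term_by_term_summation_oracle(self, rng):
        p = rng.random(6) + 0.01
        t = rng.random(6) + 0.01
        pn, tn = p / p.sum(), t / t.sum()
        mid = (pn + tn) / 2
        kl = lambda a, b: np.sum(a * np.log(a / b))
        oracle = 0.5 * kl(tn, mid) + 0.5 * kl(pn, mid)
        assert abs(js_gene(p, t) - oracle) <= 1e-12

    def test_symmetry_and_bounds(self, rng):
        for _ in range(5):
            p, t = rng.random(8), rng.random(8)
            a, b = js_gene(p, t), js_gene(t, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0 <= a <= np.log(2) + 1e-12

    def test_negative_or_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            js_gene(np.array([-1.0, 2.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            js_gene(np.zeros(3), np.ones(3))

    def test_histogram_js_on_identical_samples_is_zero(self, rng):
        a = rng.normal(size=500)
        assert js_histogram(a, a) == pytest.approx(0.0, abs=1e-12)


def brute_force_ari(a, b):
    """Pair-counting over all C(n,2) pairs."""
    n = len(a)
    same_a = same_b = same_both = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        sa, sb = a[i] == a[j], b[i] == b[j]
        same_a += sa
        same_b += sb
        same_both += sa and sb
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    return (same_both - expected) / (max_index - expected)


def entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log(p))


def mutual_information(a, b):
    n = len(a)
    mi = 0.0
    for ua in np.unique(a):
        for ub in np.unique(b):
            nij = np.sum((a == ua) & (b == ub))
            if nij:
                mi += nij / n * np.log(nij * n / (np.sum(a == ua) * np.sum(b == ub)))
    return mi


class TestClusteringMetrics:
    def test_identical_labelings_score_one(self):
        lab = np.array([0, 0, 1, 1, 2, 2])
        for fn in (ari, nmi, ami, homo):
            assert fn(lab, lab) == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([5, 5, 3, 3, 9, 9])  # same partition, renamed ids
        for fn in (ari, nmi, ami, homo):
            assert fn(a, a) == pytest.approx(fn(b, a))

    def test_ari_matches_pair_enumeration(self):
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 2, 2])
        assert ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_nmi_homo_match_direct_summation(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        b = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        mi = mutual_information(a, b)
        assert nmi(a, b) == pytest.approx(
            mi / np.sqrt(entropy(a) * entropy(b)), abs=1e-10)
        # homogeneity: 1 - H(T|P)/H(T) with truth b, prediction a
        h_t_given_p = entropy_conditional(b, a)
        assert homo(a, b) == pytest.approx(1 - h_t_given_p / entropy(b), abs=1e-10)

    def test_ami_matches_permutation_model_oracle(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        b = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        mi = mutual_information(a, b)
        emi = np.mean([
            mutual_information(np.array(perm), b)
            for perm in itertools.permutations(a)
        ])
        expected = (mi - emi) / ((entropy(a) + entropy(b)) / 2 - emi)
        assert ami(a, b) == pytest.approx(expected, abs=1e-10)

    def test_independent_labelings_near_zero_ami(self, rng):
        a = rng.integers(0, 4, 1000)
        b = rng.integers(0, 4, 1000)
        assert abs(ami(a, b)) < 0.05
        assert nmi(a, b) > ami(a, b)

    def test_single_cluster_truth_homogeneity_convention(self):
        with pytest.warns(UserWarning, match="single-cluster"):
            assert homo(np.array([0, 1, 0]), np.array([1, 1, 1])) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari(np.array([0, 1]), np.array([0, 1, 1]))


def entropy_conditional(t, p):
    n = len(t)
    h = 0.0
    for up in np.unique(p):
        sel = p == up
        w = sel.sum() / n
        h += w * entropy(t[sel])
    return h


class TestClusterCells:
    def _blobs(self, rng, n=60):
        a = rng.normal(0, 0.3, size=(n // 2, 10))
        b = rng.normal(4, 0.3, size=(n // 2, 10))
        vals = np.abs(np.vstack([a, b]))
        em = ExpressionMatrix(
            values=vals,
            gene_names=[f"g{i}" for i in range(10)],
            cell_names=[f"c{i}" for i in range(n)],
            modality="st",
        )
        truth = np.repeat([0, 1], n // 2)
        return em, truth

    def test_separable_blobs_recovered(self, rng):
        em, truth = self._blobs(rng)
        labels = cluster_cells(em, resolution=0.5, seed=0)
        assert ari(labels, truth) > 0.9

    def test_deterministic(self, rng):
        em, _ = self._blobs(rng)
        a = cluster_cells(em, seed=1)
        b = cluster_cells(em, seed=1)
        assert np.array_equal(a, b)

    def test_cluster_count_nondecreasing_in_resolution(self, rng):
        em, _ = self._blobs(rng, n=80)
        counts = [
            len(np.unique(cluster_cells(em, resolution=r, seed=0)))
            for r in (0.2, 1.0, 3.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestASScore:
    def _tidy(self, rows):
        return pd.DataFrame(rows, columns=["method", "dataset", "metric", "value"])

    def test_total_dominance(self):
        rows = []
        for ds in ("d1", "d2"):
            for met in ("spcc", "ssim"):
                rows += [("A", ds, met, 0.9), ("B", ds, met, 0.1)]
        out = as_score(self._tidy(rows))
        assert out.loc["A", "as_score"] == 2.0
        assert out.loc["B", "as_score"] == 1.0

    def test_lower_is_better_orientation(self):
        rows = [("A", "d", "rmse", 0.1), ("B", "d", "rmse", 0.9)]
        out = as_score(self._tidy(rows))
        assert out.loc["A", "as_score"] > out.loc["B", "as_score"]

    def test_hand_ranked_toy_table(self):
        rows = []
        vals = {
            ("A", "d1", "spcc"): 0.3, ("B", "d1", "spcc"): 0.2, ("C", "d1", "spcc"): 0.1,
            ("A", "d1", "js"): 0.5, ("B", "d1", "js"): 0.1, ("C", "d1", "js"): 0.3,
            ("A", "d2", "spcc"): 0.1, ("B", "d2", "spcc"): 0.2, ("C", "d2", "spcc"): 0.3,
            ("A", "d2", "js"): 0.2, ("B", "d2", "js"): 0.2, ("C", "d2", "js"): 0.9,
        }
        for (m, d, met), v in vals.items():
            rows.append((m, d, met, v))
        out = as_score(self._tidy(rows))
        # hand ranks per cell (higher rank better):
        # d1/spcc: A3 B2 C1 ; d1/js: A1 B3 C2 ; d2/spcc: A1 B2 C3
        # d2/js: A2.5 B2.5 C1 (tie averaged)
        assert out.loc["A", "as_score"] == pytest.approx((3 + 1 + 1 + 2.5) / 4)
        assert out.loc["B", "as_score"] == pytest.approx((2 + 3 + 2 + 2.5) / 4)
        assert out.loc["C", "as_score"] == pytest.approx((1 + 2 + 3 + 1) / 4)

    def test_duplicated_methods_tie(self):
        rows = [("A", "d", "spcc", 0.5), ("B", "d", "spcc", 0.5),
                ("A", "d", "js", 0.2), ("B", "d", "js", 0.2)]
        out = as_score(self._tidy(rows))
        assert out.loc["A", "as_score"] == out.loc["B", "as_score"] == 1.5
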