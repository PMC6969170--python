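"""Diversity, dissimilarity and PERMANOVA, checked against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy, kstest

import drugmwas as dm


class TestShannon:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([0.25] * 4, np.log(4)),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
        ],
    )
    def test_closed_forms(self, vec, expected):
        assert dm.shannon_index(vec) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.random(30)
            assert dm.shannon_index(v) == pytest.approx(entropy(v / v.sum()))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            dm.shannon_index([0.0, 0.0])

    def test_uniform_maximises(self):
        rng = np.random.default_rng(1)
        k = 8
        h_uniform = dm.shannon_index([1 / k] * k)
        for _ in range(50):
            v = rng.dirichlet(np.ones(k))
            assert dm.shannon_index(v) <= h_uniform + 1e-12


class TestBrayCurtis:
    def test_identity_boundary_and_hand_case(self):
        assert dm.bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert dm.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0
        assert dm.bray_curtis([0.7, 0.3], [0.3, 0.7]) == pytest.approx(0.4)

    def test_all_zero_pair_raises(self):
        with pytest.raises(ValueError):
            dm.bray_curtis([0.0, 0.0], [0.0, 0.0])

    def test_bounds_and_symmetry_on_random_compositions(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, y = rng.dirichlet(np.ones(10)), rng.dirichlet(np.ones(10))
            d = dm.bray_curtis(x, y)
            assert 0 <= d <= 1
            assert d == pytest.approx(dm.bray_curtis(y, x))

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.random((6, 5)), index=[f"s{i}" for i in range(6)])
        m = dm.bray_curtis_matrix(data)
        for i, j in itertools.combinations(range(6), 2):
            assert m.iloc[i, j] == pytest.approx(
                dm.bray_curtis(data.iloc[i], data.iloc[j])
            )


def _dist(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d, index=ids, columns=ids)


class TestPermanova:
    def test_matches_skbio_on_categorical_grouping(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(0)
        x = rng.random((24, 4))
        dist = _dist(x)
        grp = pd.Series(rng.integers(0, 3, 24).astype(str), index=dist.index, name="g")
        mine = dm.permanova(dist, grp, n_perm=999, seed=5)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dist.to_numpy(), list(dist.index)),
            grp.to_numpy(), permutations=999,
        )
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_small_sample_p_is_exact_enumeration(self):
        rng = np.random.default_rng(7)
        dist = _dist(rng.random((6, 3)))
        grp = pd.Series(["a"] * 3 + ["b"] * 3, index=dist.index, name="g")
        res = dm.permanova(dist, grp, n_perm=100_000, seed=0)
        # independent exhaustive oracle over all 6! relabelings
        d = dist.to_numpy()
        a = -0.5 * d ** 2
        g = a - a.mean(0, keepdims=True) - a.mean(1, keepdims=True) + a.mean()
        design = np.array([[1.0]] * 3 + [[0.0]] * 3)
        design -= design.mean(0)
        hat = design @ np.linalg.pinv(design)
        resid = np.eye(6) - hat

        def f(perm):
            gp = g[np.ix_(perm, perm)]
            return np.sum(hat * gp) / (np.sum(resid * gp) / 4)

        f_obs = f(range(6))
        count = sum(
            1 for perm in itertools.permutations(range(6)) if f(perm) >= f_obs - 1e-10
        )
        assert res.p == pytest.approx(count / 720, abs=1e-12)

    def test_perfect_separation(self):
        # two groups of duplicated identical points
        pts = [[0, 0]] * 3 + [[1, 1]] * 3
        dist = _dist(pts)
        grp = pd.Series(["a"] * 3 + ["b"] * 3, index=dist.index, name="g")
        res = dm.permanova(dist, grp, n_perm=720, seed=0)
        assert res.r2 == pytest.approx(1.0)
        # minimal attainable p: only group-preserving relabelings tie
        assert res.p == pytest.approx(72 / 720)

    def test_r2_equals_euclidean_anova_decomposition(self):
        # with Euclidean distances r2 must equal SS_between / SS_total of the points
        rng = np.random.default_rng(11)
        x = rng.random((30, 3))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        dist = _dist(x)
        grp = pd.Series(labels, index=dist.index, name="g")
        res = dm.permanova(dist, grp, n_perm=99, seed=0)
        grand = x.mean(0)
        ss_total = ((x - grand) ** 2).sum()
        ss_between = sum(
            (labels == lab).sum() * ((x[labels == lab].mean(0) - grand) ** 2).sum()
            for lab in ("a", "b")
        )
        assert res.r2 == pytest.approx(ss_between / ss_total, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(13)
        pvals = []
        for seed in range(200):
            x = rng.random((12, 3))
            dist = _dist(x)
            grp = pd.Series(rng.integers(0, 2, 12).astype(str), index=dist.index, name="g")
            if grp.nunique() < 2:
                continue
            pvals.append(dm.permanova(dist, grp, n_perm=199, seed=seed).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_grouping_raises(self):
        dist = _dist(np.random.default_rng(0).random((5, 2)))
        grp = pd.Series(["a"] * 5, index=dist.index, name="g")
        with pytest.raises(ValueError, match="constant"):
            dm.permanova(dist, grp, n_perm=99)

    def test_asymmetric_matrix_raises(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            dm.permanova(d, pd.Series(["x", "y"], index=["a", "b"], name="g"), n_perm=99)


class TestRichnessAssociations:
    def _meta(self, drug_vec, cohort="A"):
        n = len(drug_vec)
        ids = [f"s{i}" for i in range(n)]
        frame = pd.DataFrame(
            {"cohort": cohort, "age": 40.0, "sex": "female", "bmi": 24.0,
             "seq_depth": 2e7, "ibs_status": "no", "ibd_subtype": "none",
             "stoma_pouch": False},
            index=ids,
        )
        return dm.SampleMetadata(frame, pd.DataFrame({"d": drug_vec}, index=ids)), ids

    def test_rank_test_exact_p(self):
        meta, ids = self._meta([1, 1, 1, 0, 0, 0])
        h = pd.Series([1.0, 2, 3, 4, 5, 6], index=ids)
        res = dm.richness_drug_associations(h, meta)
        assert res[res["variable"] == "d"].iloc[0]["p"] == pytest.approx(0.1)

    def test_monotone_drug_count_gives_rho_one(self):
        n = 8
        ids = [f"s{i}" for i in range(n)]
        frame = pd.DataFrame(
            {"cohort": "A", "age": 40.0, "sex": "male", "bmi": 24.0,
             "seq_depth": 2e7, "ibs_status": "no", "ibd_subtype": "none",
             "stoma_pouch": False}, index=ids)
        drugs = pd.DataFrame(
            {f"d{j}": [1 if i >= j else 0 for i in range(n)] for j in range(n)},
            index=ids)
        meta = dm.SampleMetadata(frame, drugs)
        h = pd.Series(np.arange(n, dtype=float), index=ids)
        res = dm.richness_drug_associations(h, meta)
        row = res[res["variable"] == "n_drugs"].iloc[0]
        assert row["statistic"] == pytest.approx(1.0)

    def test_null_slope_ci_coverage(self):
        rng = np.random.default_rng(17)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 40
            drug_counts = rng.integers(0, 6, n)
            ids = [f"s{i}" for i in range(n)]
            frame = pd.DataFrame(
                {"cohort": "A", "age": 40.0, "sex": "male", "bmi": 24.0,
                 "seq_depth": 2e7, "ibs_status": "no", "ibd_subtype": "none",
                 "stoma_pouch": False}, index=ids)
            drugs = pd.DataFrame(
                {f"d{j}": (drug_counts > j).astype(int) for j in range(6)}, index=ids)
            meta = dm.SampleMetadata(frame, drugs)
            h = pd.Series(rng.normal(2.0, 0.5, n), index=ids)  # independent of drugs
            res = dm.richness_drug_associations(h, meta)
            row = res[res["variable"] == "n_drugs"].iloc[0]
            if row["slope_lo"] <= 0 <= row["slope_hi"]:
                covered += 1
        assert covered / reps >= 0.93
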