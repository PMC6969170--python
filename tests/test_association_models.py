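"""Per-cohort OLS models, checked against an independent normal-equations oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import kstest

import drugmwas as dm
from drugmwas.association_models import _covariate_design


def make_meta(n, rng, cohort="A", n_drugs=2, user_frac=0.3, scheme="population"):
    ids = [f"{cohort}_{i}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "cohort": cohort,
            "age": rng.uniform(20, 80, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "bmi": rng.uniform(18, 35, n),
            "seq_depth": rng.uniform(1e7, 4e7, n),
            "ibs_status": np.where(rng.random(n) < 0.2, "yes", "no"),
            "ibd_subtype": "none" if scheme == "population"
            else rng.choice(["CD", "UC", "IBDU"], n),
            "stoma_pouch": False,
        },
        index=ids,
    )
    drugs = pd.DataFrame(
        {f"d{j}": (rng.random(n) < user_frac).astype(int) for j in range(n_drugs)},
        index=ids,
    )
    return dm.SampleMetadata(frame, drugs)


def normal_equations_oracle(x: np.ndarray, y: np.ndarray, j: int):
    """Independent solve of the same design: beta, SE, t, p for column j."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    dof = x.shape[0] - np.linalg.matrix_rank(x)
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[j, j])
    t = beta[j] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return beta[j], se, t, p


class TestOracleEquivalence:
    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(40, 120))
            meta = make_meta(n, rng)
            y = pd.Series(rng.normal(0, 1, n), index=meta.frame.index, name="f")
            res = dm.fit_feature_model(y, meta, "d0", mode="single")
            x = pd.concat(
                [pd.Series(1.0, index=meta.frame.index, name="const"),
                 meta.drugs["d0"].astype(float),
                 _covariate_design(meta, meta.frame.index)], axis=1,
            ).to_numpy()
            b, se, t, p = normal_equations_oracle(x, y.to_numpy(), 1)
            assert res.beta == pytest.approx(b, abs=1e-8)
            assert res.se == pytest.approx(se, abs=1e-8)
            assert res.t == pytest.approx(t, abs=1e-6)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        meta = make_meta(80, rng)
        y = pd.Series(rng.normal(0, 1, 80), index=meta.frame.index, name="f")
        res = dm.fit_feature_model(y, meta, "d1", mode="multi")
        x = pd.concat(
            [_covariate_design(meta, meta.frame.index),
             meta.drugs.astype(float)], axis=1,
        )
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.beta == pytest.approx(fit.params["d1"], abs=1e-10)
        assert res.se == pytest.approx(fit.bse["d1"], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues["d1"], abs=1e-10)


class TestRecoveryAndCalibration:
    def test_known_coefficient_recovered(self):
        rng = np.random.default_rng(1)
        n = 100
        meta = make_meta(n, rng)
        y = (3.0 + 2.0 * meta.drugs["d0"] + 0.1 * meta.frame["age"]
             + rng.normal(0, 1e-4, n))
        res = dm.fit_feature_model(pd.Series(y, name="f"), meta, "d0")
        assert res.beta == pytest.approx(2.0, abs=1e-3)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        n = 120
        meta = make_meta(n, rng)
        features = dm.FeatureMatrix(
            pd.DataFrame(rng.normal(0, 1, (n, 500)), index=meta.frame.index,
                         columns=[f"f{i}" for i in range(500)]),
            "log-kept-zeros",
        )
        tab = dm.run_cohort_associations(features, meta, "single")
        pvals = tab[tab["drug"] == "d0"]["p"]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_drug_below_user_gate_fitted_only_where_eligible(self):
        rng = np.random.default_rng(3)
        meta_a = make_meta(60, rng, cohort="A")
        meta_b = make_meta(60, rng, cohort="B")
        # drug d0: 4 users in A, 10 in B
        meta_a.drugs["d0"] = [1] * 4 + [0] * 56
        meta_b.drugs["d0"] = [1] * 10 + [0] * 50
        meta = dm.SampleMetadata(
            pd.concat([meta_a.frame, meta_b.frame]),
            pd.concat([meta_a.drugs, meta_b.drugs]),
        )
        features = dm.FeatureMatrix(
            pd.DataFrame({"f": rng.normal(0, 1, 120)}, index=meta.frame.index),
            "log-kept-zeros",
        )
        tab = dm.run_cohort_associations(features, meta, "single")
        d0 = tab[tab["drug"] == "d0"]
        assert set(d0["cohort"]) == {"B"}
        assert not d0["meta_eligible"].any()  # single-cohort drug

    def test_constant_feature_flagged_degenerate(self):
        rng = np.random.default_rng(4)
        meta = make_meta(60, rng)
        features = dm.FeatureMatrix(
            pd.DataFrame({"f": np.zeros(60)}, index=meta.frame.index), "arcsine-sqrt"
        )
        tab = dm.run_cohort_associations(features, meta, "single")
        assert tab["flags"].str.contains("degenerate").all()

    def test_no_users_skipped(self):
        rng = np.random.default_rng(6)
        meta = make_meta(40, rng, n_drugs=1)
        meta.drugs["d0"] = 0
        with pytest.raises(ValueError, match="could not be fitted"):
            dm.fit_feature_model(
                pd.Series(rng.normal(0, 1, 40), index=meta.frame.index, name="f"),
                meta, "d0",
            )

    def test_ibd_cohort_uses_subtype_dummies(self):
        rng = np.random.default_rng(7)
        meta = make_meta(80, rng, scheme="ibd")
        res = dm.fit_feature_model(
            pd.Series(rng.normal(0, 1, 80), index=meta.frame.index, name="f"),
            meta, "d0",
        )
        assert "disease_UC" in res.covariates
        assert "disease_IBDU" in res.covariates
        assert "ibs_yes" not in res.covariates


class TestDeconfounding:
    def test_multi_mode_restores_null_drug_calibration(self):
        """A null drug correlated with a causal one (phi ~ 0.7) shows inflated
        |t| in single mode; adding the causal drug as covariate restores it."""
        t_single, t_multi = [], []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 250
            z = rng.multivariate_normal([0, 0], [[1, 0.85], [0.85, 1]], n)
            a = (z[:, 0] > stats.norm.ppf(0.7)).astype(int)
            b = (z[:, 1] > stats.norm.ppf(0.7)).astype(int)
            meta = make_meta(n, rng, n_drugs=2)
            meta.drugs["d0"], meta.drugs["d1"] = a, b
            y = pd.Series(0.5 * a + rng.normal(0, 1, n),
                          index=meta.frame.index, name="f")
            features = dm.FeatureMatrix(y.to_frame(), "log-kept-zeros")
            s = dm.run_cohort_associations(features, meta, "single")
            m = dm.run_cohort_associations(features, meta, "multi")
            t_single.append(abs(s[s["drug"] == "d1"].iloc[0]["t"]))
            t_multi.append(abs(m[m["drug"] == "d1"].iloc[0]["t"]))
        assert np.median(t_multi) < np.median(t_single)
        assert np.median(t_single) > 1.0  # visibly inflated by confounding
        assert np.median(t_multi) < 1.0  # near null expectation


class TestCollinearity:
    def test_perfectly_collinear_drug_dropped_and_flagged(self):
        rng = np.random.default_rng(8)
        meta = make_meta(60, rng, n_drugs=3)
        meta.drugs["d2"] = meta.drugs["d0"]  # exact duplicate exposure
        features = dm.FeatureMatrix(
            pd.DataFrame({"f": rng.normal(0, 1, 60)}, index=meta.frame.index),
            "log-kept-zeros",
        )
        tab = dm.run_cohort_associations(features, meta, "multi")
        assert tab["flags"].str.contains("collinear-dropped").all()
        # exactly one member of the collinear pair is reported
        assert len(set(tab["drug"]) & {"d0", "d2"}) == 1
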