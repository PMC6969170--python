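"""Generator calibration, determinism and construction identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, spearmanr

import drugmwas as dm


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = dm.effects_preset(11, sizes=(100, 60, 40), n_taxa=60)
        a = dm.generate(cfg)
        b = dm.generate(cfg)
        pd.testing.assert_frame_equal(a.taxa.data, b.taxa.data)
        pd.testing.assert_frame_equal(a.meta.drugs, b.meta.drugs)
        pd.testing.assert_frame_equal(a.ar_markers.data, b.ar_markers.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = dm.generate(dm.effects_preset(1, sizes=(50, 30, 20), n_taxa=40))
        b = dm.generate(dm.effects_preset(2, sizes=(50, 30, 20), n_taxa=40))
        assert not a.taxa.data.equals(b.taxa.data)


class TestCompositionStructure:
    def test_kingdom_closure_exact(self, small_effects_dataset):
        taxa = small_effects_dataset.taxa
        kingdoms = [c for c in taxa.data.columns if "|" not in c]
        np.testing.assert_allclose(taxa.data[kingdoms].sum(axis=1), 100.0, atol=1e-9)

    def test_internal_rows_are_sums_of_children(self, small_effects_dataset):
        taxa = small_effects_dataset.taxa.data
        labels = list(taxa.columns)
        for internal in labels:
            depth = internal.count("|")
            children = [l for l in labels
                        if l.startswith(internal + "|") and l.count("|") == depth + 1]
            if children:
                np.testing.assert_allclose(
                    taxa[internal], taxa[children].sum(axis=1), atol=1e-9
                )

    def test_endpoint_extraction_removes_exactly_internal_rows(self, small_effects_dataset):
        taxa = small_effects_dataset.taxa
        eps, _ = dm.extract_endpoints(taxa)
        species = [c for c in taxa.data.columns if "s__" in c.split("|")[-1]]
        assert sorted(eps.feature_ids) == sorted(species)

    def test_stratified_rows_sum_to_community_total(self, small_effects_dataset):
        ds = small_effects_dataset
        strat, comm = ds.stratified.data, ds.pathways.data
        for pwy in comm.columns:
            cols = [c for c in strat.columns if c.split("|", 1)[0] == pwy]
            np.testing.assert_allclose(
                strat[cols].sum(axis=1), comm[pwy], atol=1e-9
            )


class TestDrugMatrixCalibration:
    def test_marginal_prevalence_within_binomial_error(self):
        cfg = dm.GeneratorConfig(
            seed=0,
            cohorts=[dm.CohortSpec("population", 1124, "population")],
            drugs=[dm.DrugSpec("a", {"population": 0.08})],
            n_taxa=5, n_pathways=2,
        )
        counts = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            drugs, _, _ = dm.generate_drug_matrix(cfg, cfg.cohorts[0], rng)
            counts.append(drugs["a"].sum())
        expected = 0.08 * 1124
        sd = np.sqrt(1124 * 0.08 * 0.92)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(40)

    def test_copula_hits_target_rank_correlation(self):
        cfg = dm.GeneratorConfig(
            seed=0,
            cohorts=[dm.CohortSpec("population", 1124, "population")],
            drugs=[dm.DrugSpec("a", {"population": 0.05}),
                   dm.DrugSpec("b", {"population": 0.06})],
            drug_correlations={"a|b": 0.78},
            n_taxa=5, n_pathways=2,
        )
        rhos = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            drugs, _, _ = dm.generate_drug_matrix(cfg, cfg.cohorts[0], rng)
            rhos.append(spearmanr(drugs["a"], drugs["b"])[0])
        assert np.mean(rhos) == pytest.approx(0.78, abs=0.08)

    def test_zero_correlation_gives_independence(self):
        cfg = dm.GeneratorConfig(
            seed=0,
            cohorts=[dm.CohortSpec("population", 2000, "population")],
            drugs=[dm.DrugSpec("a", {"population": 0.3}),
                   dm.DrugSpec("b", {"population": 0.3})],
            n_taxa=5, n_pathways=2,
        )
        rng = np.random.default_rng(0)
        drugs, _, _ = dm.generate_drug_matrix(cfg, cfg.cohorts[0], rng)
        table = pd.crosstab(drugs["a"], drugs["b"])
        assert chi2_contingency(table)[1] > 0.01

    def test_infeasible_correlation_cites_frechet_bound(self):
        with pytest.raises(ValueError, match="Fréchet"):
            dm.solve_latent_correlation(0.99, 0.05, 0.5)

    def test_doses_and_subtypes_only_for_users(self, small_effects_dataset):
        meta = small_effects_dataset.meta
        users = meta.drugs["PPI"] == 1
        assert meta.dose.loc[users, "PPI"].notna().all()
        assert meta.dose.loc[~users, "PPI"].isna().all()
        assert set(meta.dose.loc[users, "PPI"]) <= {20.0, 40.0, 80.0}


class TestTruthIO:
    def test_round_trip(self, tmp_path, small_effects_dataset):
        ds = small_effects_dataset
        path = tmp_path / "truth.tsv"
        dm.write_truth(ds.truth, path, ds.config)
        back = dm.read_truth(path, ds.config)
        pd.testing.assert_frame_equal(back, ds.truth.reset_index(drop=True))

    def test_empty_truth(self, tmp_path):
        cfg = dm.null_preset(0, sizes=(30, 20, 10), n_taxa=20)
        ds = dm.generate(cfg)
        assert ds.truth.empty
        path = tmp_path / "truth.tsv"
        dm.write_truth(ds.truth, path, cfg)
        assert dm.read_truth(path, cfg).empty

    def test_hash_mismatch_rejected(self, tmp_path, small_effects_dataset):
        ds = small_effects_dataset
        path = tmp_path / "truth.tsv"
        dm.write_truth(ds.truth, path, ds.config)
        other = dm.null_preset(99, sizes=(30, 20, 10), n_taxa=20)
        with pytest.raises(ValueError, match="hash"):
            dm.read_truth(path, other)


class TestEffectInjection:
    def test_injection_shifts_transformed_scale_by_delta(self):
        """For users, the arcsine-sqrt value of the target taxon is shifted by
        exactly the recorded absolute effect relative to the same draw without
        effects (same seed, effects removed)."""
        cfg = dm.effects_preset(5, sizes=(150, 5, 5), n_taxa=60)
        cfg.effects = cfg.effects[:1]  # isolate a single injected effect
        ds = dm.generate(cfg)
        cfg_null = dm.effects_preset(5, sizes=(150, 5, 5), n_taxa=60)
        cfg_null.effects = []
        ds0 = dm.generate(cfg_null)
        t = ds.truth.iloc[0]
        users = ds.meta.drugs[t["drug"]] == 1
        feat = t["feature"]
        with_eff = np.arcsin(np.sqrt(ds.taxa.data[feat] / 100.0))
        without = np.arcsin(np.sqrt(ds0.taxa.data[feat] / 100.0))
        shift = (with_eff - without)[users.to_numpy()]
        np.testing.assert_allclose(shift, t["effect_abs"], atol=1e-9)
        # non-users untouched on the target taxon
        np.testing.assert_allclose(
            (with_eff - without)[~users.to_numpy()], 0.0, atol=1e-12
        )

    def test_recovered_beta_close_to_truth(self, small_effects_dataset):
        ds = small_effects_dataset
        taxa, meta, _ = dm.apply_sample_exclusions(ds.taxa, ds.meta)
        eps, _ = dm.extract_endpoints(dm.taxa_to_proportions(taxa))
        filt, _ = dm.filter_taxa(eps, meta.cohorts)
        fm = dm.transform_taxa(filt)
        tab = dm.run_cohort_associations(fm, meta, "single")
        out = dm.meta_analyze(tab)
        errs = []
        for _, t in ds.truth.iterrows():
            row = out[(out["drug"] == t["drug"]) & (out["feature"] == t["feature"])]
            if len(row):
                errs.append(row.iloc[0]["beta_meta"] / t["effect_abs"] - 1.0)
        assert abs(np.mean(errs)) < 0.25
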