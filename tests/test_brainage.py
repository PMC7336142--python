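"""Tests of stratified subsampling, the SVR weak learner and BrainAGE scoring."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import parcelbrain as pb
from parcelbrain.brainage import SVRHyper, WeakLearner


def reference_cohort(n, seed=0, n_sites=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"r{i}" for i in range(n)],
            "age": rng.uniform(55, 85, n),
            "sex": rng.choice(["female", "male"], n),
            "diagnosis": "HC",
            "sdb_status": pd.Series([pd.NA] * n, dtype="object"),
            "bmi": rng.normal(27, 4, n),
            "education_years": rng.normal(14, 3, n),
            "apoe4_count": rng.choice([0, 1, 2], n),
            "site": rng.choice([f"S{k}" for k in range(n_sites)], n),
            "protocol": "native",
            "field_strength": "3T",
            "treatment_flag": False,
        }
    )


class TestStratifiedSubsample:
    def test_stratum_cap_applied(self):
        """A cell with more than max_per_stratum eligible subjects yields
        exactly max_per_stratum draws."""
        cohort = reference_cohort(600, seed=1, n_sites=1)
        cohort["age"] = np.where(np.arange(600) < 500, 57.0, 80.0)  # two brackets
        cohort["sex"] = np.where(np.arange(600) % 2 == 0, "female", "male")
        config = pb.StratificationConfig(max_per_stratum=30, per_replicate_fraction=1.0, seed=0)
        ids = pb.stratified_subsample(cohort, config, 1)
        sub = cohort.set_index("subject_id").loc[ids]
        counts = sub.groupby([config.bracket_of(sub["age"].to_numpy()), "sex"]).size()
        assert (counts <= 30).all()
        assert counts.max() == 30

    def test_no_duplicates_and_sex_equalized(self):
        cohort = reference_cohort(400, seed=2)
        config = pb.StratificationConfig(per_replicate_fraction=1.0, seed=0)
        ids = pb.stratified_subsample(cohort, config, 3)
        assert len(ids) == len(set(ids))
        sub = cohort.set_index("subject_id").loc[ids]
        brackets = config.bracket_of(sub["age"].to_numpy())
        for b in np.unique(brackets):
            by_sex = sub[brackets == b]["sex"].value_counts()
            assert by_sex.max() == by_sex.min()

    def test_inclusion_frequencies_uniform_within_cell(self):
        """Over many replicates, eligible subjects of one over-full cell are
        included with equal frequency (exchangeability oracle)."""
        cohort = reference_cohort(120, seed=3, n_sites=1)
        cohort["age"] = 60.0
        cohort["sex"] = ["female", "male"] * 60
        config = pb.StratificationConfig(max_per_stratum=20, seed=0)
        # need a second occupied bracket for validity
        cohort.loc[:9, "age"] = 82.0
        counts = pd.Series(0, index=cohort["subject_id"])
        n_rep = 500
        rng = np.random.default_rng(11)
        for _ in range(n_rep):
            for sid in pb.stratified_subsample(cohort, config, rng):
                counts[sid] += 1
        young = cohort.loc[cohort["age"] == 60.0, "subject_id"]
        freq = counts[young] / n_rep
        p = freq.mean()
        band = 4 * np.sqrt(p * (1 - p) / n_rep)
        assert (np.abs(freq - p) < band).mean() > 0.95

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pb.stratified_subsample(reference_cohort(0), pb.StratificationConfig(), 0)


class TestWeakLearner:
    def test_noise_free_linear_signal_recovered_within_epsilon(self):
        """Exactly linear age signal, no noise: a weakly regularized SVR
        attains the zero-loss solution, so training predictions lie within
        epsilon (+ solver slack) of the true ages."""
        rng = np.random.default_rng(4)
        n, p = 80, 10
        ages = rng.uniform(55, 85, n)
        W = rng.standard_normal((p,))
        X = 1000 + np.outer(ages - 55, W) + rng.standard_normal((n, p)) * 0  # noise-free
        hyper = SVRHyper(C=1e4, epsilon=0.1, tol=1e-6, max_iter=200000)
        learner = pb.fit_weak_learner(X, ages, hyper, random_state=0)
        pred = learner.predict(X)
        assert np.max(np.abs(pred - ages)) < 0.1 + 1e-3

    def test_feature_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        n, p = 60, 8
        ages = rng.uniform(55, 85, n)
        X = rng.standard_normal((n, p)) + ages[:, None] * 0.1
        l1 = pb.fit_weak_learner(X, ages, random_state=1)
        X2 = X.copy()
        X2[:, 3] *= 10.0
        l2 = pb.fit_weak_learner(X2, ages, random_state=1)
        np.testing.assert_allclose(l1.predict(X), l2.predict(X2), atol=1e-6)

    def test_deterministic_given_data_and_seed(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 5))
        ages = rng.uniform(55, 85, 50)
        p1 = pb.fit_weak_learner(X, ages, random_state=3).predict(X)
        p2 = pb.fit_weak_learner(X, ages, random_state=3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_feature_floored_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 4))
        X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant feature"):
            learner = pb.fit_weak_learner(X, rng.uniform(55, 85, 40))
        assert learner.scale[2] == 1.0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="at least 20"):
            pb.fit_weak_learner(rng.standard_normal((10, 3)), rng.uniform(55, 85, 10))


class TestEnsemble:
    def _toy_ensemble(self, learners):
        return pb.AgePredictionEnsemble(
            learners=learners,
            parcel_ids=[f"p{j}" for j in range(3)],
            config=pb.StratificationConfig(n_replicates=len(learners)),
            hyper=SVRHyper(),
        )

    def _learner(self, seed):
        rng = np.random.default_rng(seed)
        return WeakLearner(
            center=rng.standard_normal(3),
            scale=np.abs(rng.standard_normal(3)) + 0.5,
            coef=rng.standard_normal(3),
            intercept=70.0,
        )

    def test_single_learner_bag_is_identity(self):
        learner = self._learner(0)
        ens = self._toy_ensemble([learner])
        X = np.random.default_rng(1).standard_normal((6, 3))
        m = pb.ParcelMatrix(X, ens.parcel_ids, [f"s{i}" for i in range(6)])
        np.testing.assert_allclose(pb.predict_ensemble(ens, m), learner.predict(X))

    def test_identical_learners_bag_to_individual(self):
        learner = self._learner(2)
        ens = self._toy_ensemble([learner] * 7)
        X = np.random.default_rng(3).standard_normal((5, 3))
        m = pb.ParcelMatrix(X, ens.parcel_ids, [f"s{i}" for i in range(5)])
        np.testing.assert_allclose(pb.predict_ensemble(ens, m), learner.predict(X))

    def test_bagged_mae_bounded_by_mean_individual_mae(self):
        """Jensen: MAE of the average prediction never exceeds the average
        of the individual MAEs."""
        learners = [self._learner(s) for s in range(5)]
        ens = self._toy_ensemble(learners)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 3))
        truth = rng.uniform(55, 85, 30)
        m = pb.ParcelMatrix(X, ens.parcel_ids, [f"s{i}" for i in range(30)])
        bagged_mae = np.mean(np.abs(pb.predict_ensemble(ens, m) - truth))
        individual = np.mean([np.mean(np.abs(w.predict(X) - truth)) for w in learners])
        assert bagged_mae <= individual + 1e-12

    def test_prediction_invariant_to_learner_order(self):
        learners = [self._learner(s) for s in range(4)]
        X = np.random.default_rng(5).standard_normal((8, 3))
        m = pb.ParcelMatrix(X, [f"p{j}" for j in range(3)], [f"s{i}" for i in range(8)])
        p1 = pb.predict_ensemble(self._toy_ensemble(learners), m)
        p2 = pb.predict_ensemble(self._toy_ensemble(learners[::-1]), m)
        np.testing.assert_allclose(p1, p2)

    def test_feature_mismatch_rejected(self):
        ens = self._toy_ensemble([self._learner(0)])
        m = pb.ParcelMatrix(
            np.zeros((2, 2)), ["a", "b"], ["s0", "s1"]
        )
        with pytest.raises(ValueError, match="feature"):
            pb.predict_ensemble(ens, m)


class TestBrainageScores:
    def test_definition_and_linearity(self):
        np.testing.assert_allclose(pb.brainage_scores(np.array([80.0]), np.array([74.0])), [6.0])
        pred = np.array([70.0, 75.0, 80.0])
        chron = np.array([68.0, 77.0, 80.0])
        scores = pb.brainage_scores(pred, chron)
        np.testing.assert_allclose(scores, pred - chron)
        assert scores.mean() + chron.mean() == pytest.approx(pred.mean(), abs=1e-12)

    def test_identical_ages_give_zero(self):
        ages = np.linspace(60, 80, 9)
        np.testing.assert_array_equal(pb.brainage_scores(ages, ages), np.zeros(9))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            pb.brainage_scores(np.zeros(3), np.zeros(4))


class TestEvaluateGroups:
    def _study(self, n=90, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(56, 92, n),
                "sex": rng.choice(["female", "male"], n),
                "diagnosis": rng.choice(["HC", "MCI", "AD"], n),
                "sdb_status": rng.choice(["negative", "positive"], n),
                "bmi": 29.0,
                "education_years": 16.0,
                "apoe4_count": 0,
                "site": "A",
                "protocol": "MP-RAGE",
                "field_strength": "3T",
                "treatment_flag": False,
            }
        )

    def test_perfect_predictions(self):
        cohort = self._study()
        result = pb.evaluate_groups(cohort["age"].to_numpy(), cohort, n_perm=150, seed=0)
        assert (result.group_summary["mae"] == 0).all()
        assert (result.group_summary["mean_brainage"] == 0).all()
        assert (result.group_summary["ci_low"] == result.group_summary["ci_high"]).all()
        assert result.group_summary["note"].str.contains("degenerate").all()

    def test_t_ci_matches_bootstrap_oracle(self):
        """t-based 95% CI endpoints agree with a nonparametric bootstrap
        percentile CI on Gaussian synthetic scores (within 10% of width)."""
        rng = np.random.default_rng(9)
        cohort = self._study(n=150, seed=9)
        scores = rng.normal(2.0, 3.0, 150)
        predicted = cohort["age"].to_numpy() + scores
        result = pb.evaluate_groups(predicted, cohort, n_perm=150, seed=0)
        for _, row in result.group_summary.iterrows():
            g_scores = scores[(cohort["diagnosis"] == row["diagnosis"]).to_numpy()]
            boots = np.array(
                [rng.choice(g_scores, len(g_scores)).mean() for _ in range(10000)]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            width = row["ci_high"] - row["ci_low"]
            assert abs(row["ci_low"] - lo) < 0.15 * width
            assert abs(row["ci_high"] - hi) < 0.15 * width

    def test_group_identity_mean_predicted(self):
        cohort = self._study(n=60, seed=10)
        predicted = cohort["age"].to_numpy() + np.random.default_rng(11).normal(0, 2, 60)
        result = pb.evaluate_groups(predicted, cohort, n_perm=150, seed=0)
        for _, row in result.group_summary.iterrows():
            mask = (cohort["diagnosis"] == row["diagnosis"]).to_numpy()
            assert row["mean_brainage"] + cohort.loc[mask, "age"].mean() == pytest.approx(
                predicted[mask].mean(), abs=1e-9
            )

    def test_small_group_ci_omitted_with_notice(self):
        cohort = self._study(n=60, seed=12)
        cohort.loc[:, "diagnosis"] = "MCI"
        cohort.loc[0, "diagnosis"] = "AD"
        predicted = cohort["age"].to_numpy() + 1.0
        result = pb.evaluate_groups(predicted, cohort, n_perm=150, seed=0)
        ad = result.group_summary.set_index("diagnosis").loc["AD"]
        assert np.isnan(ad["ci_low"])
        assert "fewer than 2" in ad["note"]

    def test_sdb_type_one_error_calibrated(self):
        """With no SDB effect in the scores, the permutation ANOVA of
        BrainAGE rejects the SDB factor at about the nominal 5% rate."""
        rng = np.random.default_rng(13)
        rejections = 0
        n_sim = 120
        for k in range(n_sim):
            cohort = self._study(n=72, seed=100 + k)
            predicted = cohort["age"].to_numpy() + rng.normal(0, 3, 72)
            result = pb.evaluate_groups(predicted, cohort, n_perm=200, seed=k)
            p_sdb = result.anova.set_index("factor").loc["sdb", "p"]
            rejections += p_sdb < 0.05
        rate = rejections / n_sim
        lo, hi = stats.binom.interval(0.999, n_sim, 0.05)
        assert lo / n_sim <= rate <= hi / n_sim


class TestHarmonization:
    def test_site_offsets_removed_exactly_in_noise_free_case(self):
        """Pure additive site offsets on a covariate-explained signal are
        removed exactly, preserving the subject-weighted grand level."""
        cohort = reference_cohort(90, seed=30, n_sites=3)
        rng = np.random.default_rng(31)
        age = cohort["age"].to_numpy()
        base = 100.0 + np.outer(age - age.mean(), rng.standard_normal(5))
        site_const = {"S0": 10.0, "S1": -4.0, "S2": 2.5}
        shift = np.array([site_const[s] for s in cohort["site"]])
        parcels = pb.ParcelMatrix(
            base + shift[:, None], [f"p{j}" for j in range(5)], cohort["subject_id"]
        )
        harmonized = pb.harmonize_sites(parcels, cohort, covariates=("age",))
        expected = base + shift.mean()
        np.testing.assert_allclose(harmonized.values, expected, atol=1e-8)

    def test_joint_harmonization_aligns_cohort_levels(self):
        """A constant level shift between two cohorts is absorbed into the
        site estimates, so both end on a common basis."""
        ref = reference_cohort(120, seed=32, n_sites=2)
        test = reference_cohort(80, seed=33, n_sites=2)
        test["subject_id"] = "t_" + test["subject_id"]
        rng = np.random.default_rng(34)
        W = rng.standard_normal(4)
        make = lambda cohort, shift: pb.ParcelMatrix(
            50.0 + np.outer(cohort["age"].to_numpy() - 70.0, W) + shift,
            [f"p{j}" for j in range(4)],
            cohort["subject_id"],
        )
        ref_p, test_p = make(ref, 0.0), make(test, 25.0)
        ref_h, test_h = pb.harmonize_cohorts(ref_p, ref, test_p, test, covariates=("age",))
        # after harmonization the age-adjusted levels agree across cohorts
        ref_resid = ref_h.values - np.outer(ref["age"].to_numpy() - 70.0, W)
        test_resid = test_h.values - np.outer(test["age"].to_numpy() - 70.0, W)
        np.testing.assert_allclose(
            ref_resid.mean(axis=0), test_resid.mean(axis=0), atol=1e-8
        )

    def test_shared_subject_ids_rejected(self):
        cohort = reference_cohort(40, seed=35)
        parcels = pb.ParcelMatrix(
            np.zeros((40, 2)) + 1.0, ["a", "b"], cohort["subject_id"]
        )
        with pytest.raises(ValueError, match="share subject ids"):
            pb.harmonize_cohorts(parcels, cohort, parcels, cohort)


class TestTrainEnsembleIntegration:
    def test_reproducible_and_serializable(self, tmp_path):
        cfg = pb.SimulationConfig(n_reference=300, n_parcels=25, seed=77)
        cohort, parcels = pb.generate_reference_cohort(cfg)
        strat = pb.StratificationConfig(n_replicates=3, seed=5)
        e1 = pb.train_ensemble(cohort, parcels, strat, bias_correction=False)
        e2 = pb.train_ensemble(cohort, parcels, strat, bias_correction=False)
        m = parcels
        np.testing.assert_array_equal(pb.predict_ensemble(e1, m), pb.predict_ensemble(e2, m))
        from parcelbrain.brainage import load_ensemble, save_ensemble

        save_ensemble(e1, tmp_path / "model")
        loaded = load_ensemble(tmp_path / "model")
        np.testing.assert_allclose(
            pb.predict_ensemble(loaded, m), pb.predict_ensemble(e1, m), rtol=1e-12
        )

    def test_standardization_is_per_learner(self):
        cfg = pb.SimulationConfig(n_reference=250, n_parcels=20, seed=78)
        cohort, parcels = pb.generate_reference_cohort(cfg)
        ens = pb.train_ensemble(
            cohort, parcels, pb.StratificationConfig(n_replicates=2, seed=6), bias_correction=False
        )
        by_id = {s: i for i, s in enumerate(parcels.subject_ids)}
        for w in ens.learners:
            rows = [by_id[s] for s in w.train_ids]
            np.testing.assert_allclose(w.center, parcels.values[rows].mean(axis=0), rtol=1e-10)
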