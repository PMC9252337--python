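"""Imputation, derived exposure features, observation construction and
standardization, including the leak-freedom contracts."""

import numpy as np
import pytest

from icdpred import (
    Cohort,
    MedicationInterval,
    Standardizer,
    baseline_mean_impute,
    baseline_means,
    build_observations,
    derive_da_features,
    forward_fill,
    impute,
)
from icdpred.features import ImputationError, LeakageError, SchemaError

from conftest import make_subject, make_visit


def cohort_with_anxiety(values, sid="A1"):
    visits = [
        make_visit(float(k), 0, anxiety=v) for k, v in enumerate(values)
    ]
    subj = make_subject(sid)
    subj.visits = visits
    return Cohort([subj])


class TestForwardFill:
    @pytest.mark.parametrize(
        "before, after",
        [
            ((5, np.nan, np.nan, 7), (5, 5, 5, 7)),
            ((1, 2, 3), (1, 2, 3)),
            ((np.nan, 3, np.nan), (np.nan, 3, 3)),
        ],
    )
    def test_fill_rule(self, before, after):
        out = forward_fill(cohort_with_anxiety(before))
        got = [v.anxiety for v in out.subjects[0].visits]
        assert got == pytest.approx(after, nan_ok=True)

    def test_idempotent(self):
        c = cohort_with_anxiety((np.nan, 4, np.nan, np.nan))
        once = forward_fill(c)
        twice = forward_fill(once)
        assert once.to_frames()[0].equals(twice.to_frames()[0])

    def test_input_not_mutated(self):
        c = cohort_with_anxiety((5, np.nan))
        forward_fill(c)
        assert np.isnan(c.subjects[0].visits[1].anxiety)


class TestBaselineMeanImpute:
    def test_substitutes_training_mean_at_baseline(self):
        c = cohort_with_anxiety((np.nan, 4.0))
        out = baseline_mean_impute(
            c, {"anxiety": 6.8, "depression": 0, "rem": 0, "updrs3": 0}
        )
        assert out.subjects[0].visits[0].anxiety == 6.8

    def test_no_missing_is_identity(self, tiny_cohort):
        means = baseline_means(tiny_cohort)
        out = baseline_mean_impute(tiny_cohort, means)
        assert out.to_frames()[0].equals(tiny_cohort.to_frames()[0])

    def test_means_computed_from_named_subjects_only(self, tiny_cohort):
        all_means = baseline_means(tiny_cohort)
        sub_means = baseline_means(tiny_cohort, subject_ids=["X1"])
        x1 = tiny_cohort.subjects[0].visits[0]
        assert sub_means["anxiety"] == x1.anxiety
        assert set(all_means) == set(sub_means)

    def test_all_missing_training_baseline_raises_with_name(self):
        c = cohort_with_anxiety((np.nan, 4.0))
        with pytest.raises(ImputationError, match="anxiety"):
            baseline_means(c)

    def test_pipeline_totality(self, small_cohort):
        """After forward fill + baseline means no missing value remains."""
        cohort, _ = small_cohort
        out = impute(cohort, baseline_means(cohort))
        for s in out.subjects:
            for v in s.visits:
                for name in ("anxiety", "depression", "rem", "updrs3"):
                    assert not np.isnan(v.scale_value(name))


class TestDAFeatures:
    def test_no_exposure(self):
        assert derive_da_features([], 3.0) == (0, 0, 0, 0)

    def test_constant_dose(self):
        iv = [MedicationInterval("dopamine_agonist", 0.0, 2.0, 100.0)]
        assert derive_da_features(iv, 2.0) == (100.0, 100.0, 200.0, 2.0)

    def test_piecewise_integral(self):
        iv = [
            MedicationInterval("dopamine_agonist", 0.0, 1.0, 100.0),
            MedicationInterval("dopamine_agonist", 1.0, 2.0, 300.0),
        ]
        mean_d, max_d, tot, dur = derive_da_features(iv, 1.5)
        assert (max_d, tot, dur) == (300.0, 250.0, 1.5)
        assert mean_d == pytest.approx(250.0 / 1.5)

    def test_other_drug_classes_ignored(self):
        iv = [MedicationInterval("levodopa", 0.0, 2.0, 400.0)]
        assert derive_da_features(iv, 2.0) == (0, 0, 0, 0)

    def test_monotone_in_t_except_mean(self):
        iv = [
            MedicationInterval("dopamine_agonist", 0.5, 1.5, 200.0),
            MedicationInterval("dopamine_agonist", 2.0, 3.0, 50.0),
        ]
        prev = (0.0, 0.0, 0.0)
        for t in np.linspace(0, 4, 41):
            _, max_d, tot, dur = derive_da_features(iv, float(t))
            assert max_d >= prev[0] and tot >= prev[1] - 1e-12 and dur >= prev[2]
            prev = (max_d, tot, dur)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            derive_da_features([], -0.1)


class TestBuildObservations:
    def test_count_identity(self, small_cohort, small_obs):
        cohort, _ = small_cohort
        expected = sum(s.n_visits - 1 for s in cohort)
        assert small_obs.n_obs == expected

    def test_two_visit_subject_yields_one_observation(self, tiny_cohort):
        obs = build_observations(tiny_cohort)
        x2 = obs.subset_subjects(["X2"])
        assert x2.n_obs == 1
        assert x2.y[0] == tiny_cohort.subjects[1].visits[1].icd
        assert x2.lengths[0] == 1

    def test_subject_order_invariance(self, tiny_cohort):
        obs1 = build_observations(tiny_cohort)
        reordered = Cohort(tiny_cohort.subjects[::-1], tiny_cohort.dialect)
        obs2 = build_observations(reordered)
        key = lambda o: sorted(
            (str(o.subject_ids[i]), int(o.t_index[i]), int(o.y[i]))
            for i in range(o.n_obs)
        )
        assert key(obs1) == key(obs2)

    def test_history_contains_no_future_visits(self, tiny_cohort):
        obs = build_observations(tiny_cohort)
        icd_col = obs.clinical_names.index("icd")
        follow_col = obs.clinical_names.index("followup_length")
        for i in range(obs.n_obs):
            t = obs.lengths[i]
            sid = obs.subject_ids[i]
            subj = next(s for s in tiny_cohort if s.subject_id == sid)
            # history ICD column equals the statuses of visits 1..t
            got = obs.X_hist[i, :t, icd_col]
            assert got.tolist() == [v.icd for v in subj.visits[:t]]
            # follow-up length at the last history visit is its time
            assert obs.X_hist[i, t - 1, follow_col] == subj.visits[t - 1].time_years

    def test_missing_values_rejected(self):
        c = cohort_with_anxiety((np.nan, 4.0))
        with pytest.raises(ImputationError):
            build_observations(c)


class TestStandardizer:
    def test_train_z_scores(self, small_obs):
        std = Standardizer().fit(small_obs)
        out = std.transform(small_obs)
        m = out.mask()
        assert np.abs(out.X_hist[m].mean(axis=0)).max() < 1e-9
        assert np.abs(out.X_hist[m].std(axis=0) - 1).max() < 1e-9
        assert np.abs(out.X_static.mean(axis=0)).max() < 1e-9

    def test_known_column(self):
        x = np.array([1.0, 2.0, 3.0])
        z = (x - x.mean()) / x.std()
        assert z == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_refit_on_transformed_is_identity(self, small_obs):
        std = Standardizer().fit(small_obs)
        once = std.transform(small_obs)
        std2 = Standardizer().fit(once)
        assert np.abs(std2.clin_mean_).max() < 1e-9
        assert np.abs(std2.clin_sd_ - 1).max() < 1e-9

    def test_inverse_roundtrip(self, small_obs):
        std = Standardizer().fit(small_obs)
        back = std.inverse_transform(std.transform(small_obs))
        m = small_obs.mask()
        assert np.allclose(back.X_hist[m], small_obs.X_hist[m])
        assert np.allclose(back.X_static, small_obs.X_static)

    def test_constant_column_warns_and_centers(self, tiny_cohort):
        obs = build_observations(tiny_cohort)  # sex constant in fixture
        with pytest.warns(UserWarning, match="zero-variance"):
            std = Standardizer().fit(obs)
        out = std.transform(obs)
        j = obs.static_names.index("sex")
        assert np.allclose(out.X_static[:, j], 0.0)

    def test_leakage_audit(self, small_obs):
        half = np.unique(small_obs.subject_ids.astype(str))[:30]
        train = small_obs.subset_subjects(half)
        test = small_obs.subset_subjects(
            set(map(str, small_obs.subject_ids)) - set(half)
        )
        std = Standardizer().fit(train)
        std.assert_disjoint_from(test)  # fine
        with pytest.raises(LeakageError):
            std.assert_disjoint_from(train)

    def test_schema_mismatch_names_column(self, small_obs, tiny_cohort):
        std = Standardizer().fit(small_obs)
        other = build_observations(tiny_cohort)  # 2 SNPs instead of 31
        with pytest.raises(SchemaError):
            std.transform(other)
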