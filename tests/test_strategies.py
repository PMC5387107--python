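"""Tests for the AI/BR/BU prediction regimes and patient-coherent CV."""

import copy

import numpy as np
import pytest

import modelspace as ms
from modelspace._exceptions import ConfigurationError


def dist_tuple(d: ms.PredictiveDistribution) -> tuple:
    return (d.location, d.scale_sq, d.nu)


@pytest.fixture()
def subject(rng) -> ms.Subject:
    cfg = ms.CohortConfig(n_subjects=1, appointment_range=(6, 6), seed=99)
    return ms.generate_cohort(cfg).subjects[0]


@pytest.fixture()
def profile_and_prior(small_cohort, default_prior):
    pool = ms.fit_pool(small_cohort.subjects[:30], default_prior, 0)
    profile = ms.method2_profile(pool, small_cohort.subjects[35].baseline)
    return profile, default_prior


class TestMakeFolds:
    def test_157_subjects_10_folds_sizes(self):
        folds = ms.make_folds([f"s{i}" for i in range(157)], 10, seed=3)
        sizes = sorted(
            len(folds.validation_ids(f)) for f in range(1, 11)
        )
        assert sizes == [15, 15, 15, 16, 16, 16, 16, 16, 16, 16]

    def test_deterministic_and_partitioning(self):
        ids = [f"s{i}" for i in range(23)]
        a = ms.make_folds(ids, 4, seed=5)
        b = ms.make_folds(ids, 4, seed=5)
        assert a.mapping == b.mapping
        union = [sid for f in range(1, 5) for sid in a.validation_ids(f)]
        assert sorted(union) == sorted(ids)

    def test_k_exceeding_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            ms.make_folds(["a", "b"], 3, seed=0)


class TestPredictCourse:
    def test_first_appointment_identical_across_strategies(
        self, subject, profile_and_prior
    ):
        profile, prior = profile_and_prior
        firsts = {
            s: dist_tuple(ms.predict_course(subject, s, profile, prior)[0])
            for s in ("AI", "BR", "BU")
        }
        assert firsts["AI"] == firsts["BR"] == firsts["BU"]

    def test_ai_constant_doses_give_constant_predictions(
        self, profile_and_prior, rng
    ):
        profile, prior = profile_and_prior
        s = ms.Subject(
            "const",
            rng.standard_normal(14),
            np.tile([1.5, 0, 0, 0], (5, 1)),
            rng.standard_normal((5, 2)),
        )
        preds = ms.predict_course(s, "AI", profile, prior)
        assert len({dist_tuple(d) for d in preds}) == 1

    def test_bu_matches_batch_update_oracle(self, subject, profile_and_prior):
        """BU's prediction at appointment a equals prediction from the
        profile batch-updated on appointments 1..a-1 (conjugacy)."""
        profile, prior = profile_and_prior
        preds = ms.predict_course(subject, "BU", profile, prior, dimension=1)
        X = subject.design()
        y = subject.outcomes[:, 1]
        for a in range(subject.n_appointments):
            ref_state = ms.nig_update(profile, ms.DesignBlock(X[:a], y[:a]))
            ref = ms.posterior_predictive(ref_state, X[a])
            assert preds[a].location == pytest.approx(ref.location, abs=1e-9)
            assert preds[a].scale_sq == pytest.approx(ref.scale_sq, rel=1e-9)
            assert preds[a].nu == pytest.approx(ref.nu)

    def test_br_refits_from_elicited_prior(self, subject, profile_and_prior):
        profile, prior = profile_and_prior
        preds = ms.predict_course(subject, "BR", profile, prior)
        X = subject.design()
        y = subject.outcomes[:, 0]
        for a in range(1, subject.n_appointments):
            ref_state = ms.nig_update(prior, ms.DesignBlock(X[:a], y[:a]))
            ref = ms.posterior_predictive(ref_state, X[a])
            assert dist_tuple(preds[a]) == pytest.approx(dist_tuple(ref), rel=1e-12)

    def test_br_equals_bu_when_profile_is_the_prior(self, subject, default_prior):
        """With coinciding priors the two incremental regimes give the same
        posterior at every appointment (conjugate batch/sequential identity)."""
        br = ms.predict_course(subject, "BR", default_prior, default_prior)
        bu = ms.predict_course(subject, "BU", default_prior, default_prior)
        for a, b in zip(br, bu):
            assert dist_tuple(a) == pytest.approx(dist_tuple(b), rel=1e-9)

    @pytest.mark.parametrize("strategy", ["AI", "BR", "BU"])
    def test_prequential_no_future_leakage(
        self, subject, profile_and_prior, strategy
    ):
        """Perturbing the outcome at appointment a leaves predictions at
        appointments 1..a unchanged."""
        profile, prior = profile_and_prior
        base = ms.predict_course(subject, strategy, profile, prior)
        a_perturb = 3  # 0-based
        tampered = copy.deepcopy(subject)
        tampered.outcomes[a_perturb, 0] += 10.0
        new = ms.predict_course(tampered, strategy, profile, prior)
        for a in range(a_perturb + 1):
            assert dist_tuple(base[a]) == dist_tuple(new[a])

    @pytest.mark.parametrize("strategy", ["BR", "BU"])
    def test_missing_outcome_skipped_but_still_predicted(
        self, subject, profile_and_prior, strategy
    ):
        profile, prior = profile_and_prior
        holey = copy.deepcopy(subject)
        holey.outcomes[2, 0] = np.nan
        preds = ms.predict_course(holey, strategy, profile, prior)
        assert len(preds) == subject.n_appointments
        assert np.isfinite([d.location for d in preds]).all()
        # the missing visit contributes no update: predictions at the next
        # appointment match a course with that visit's update removed
        if strategy == "BU":
            X = holey.design()
            y = holey.outcomes[:, 0]
            seen = np.isfinite(y[:3])
            ref_state = ms.nig_update(
                profile, ms.DesignBlock(X[:3][seen], y[:3][seen])
            )
            ref = ms.posterior_predictive(ref_state, X[3])
            assert preds[3].location == pytest.approx(ref.location, abs=1e-9)


class TestRunCrossval:
    def test_validation_isolation(self, small_cohort, default_prior):
        """Perturbing one validation subject's outcomes changes only that
        subject's predictions; fitted pools exclude validation data."""
        res = ms.run_crossval(
            small_cohort, default_prior, k=4, seed=2, method=2, strategy="BU",
            dimensions=(0,),
        )
        target = small_cohort.subjects[7]
        fold = res.folds.fold_of(target.subject_id)
        tampered = copy.deepcopy(small_cohort)
        tampered.subjects[7].outcomes[:, 0] += 5.0
        res2 = ms.run_crossval(
            tampered, default_prior, k=4, seed=2, method=2, strategy="BU",
            dimensions=(0,),
        )
        merged = res.predictions.merge(
            res2.predictions,
            on=["subject_id", "appointment", "dimension"],
            suffixes=("_a", "_b"),
        )
        # within the perturbed subject's own validation fold, every other
        # subject's predictions are untouched (the subject is training data
        # in the remaining folds, so those folds may legitimately move)
        others = merged[
            (merged["subject_id"] != target.subject_id)
            & (merged["fold_a"] == fold)
        ]
        assert len(others) > 0
        assert np.array_equal(others["y_hat_a"], others["y_hat_b"])
        # fold pools exclude the validation subject entirely
        pool_ids = {m.subject_id for m in res.pools[(fold, 0)]}
        assert target.subject_id not in pool_ids

    def test_leave_one_out_runs(self, default_prior):
        cohort = ms.generate_cohort(ms.CohortConfig(n_subjects=6, seed=8))
        res = ms.run_crossval(
            cohort, default_prior, k=6, seed=1, method=2, strategy="AI",
            dimensions=(0,),
        )
        assert set(res.predictions["subject_id"]) == {
            s.subject_id for s in cohort
        }

    def test_noiseless_linear_cohort_method1_ai_near_zero_rms(self):
        from conftest import structured_linear_cohort

        cohort, prior = structured_linear_cohort(n_subjects=120, seed=23)
        res = ms.run_crossval(
            cohort, prior, k=4, seed=6, method=1, strategy="AI", dimensions=(0,)
        )
        assert ms.rms_error(res.subject_pairs(0)) < 0.05

    def test_fold_metadata_recorded(self, small_cohort, default_prior):
        res = ms.run_crossval(
            small_cohort, default_prior, k=4, seed=2, strategy="AI",
            dimensions=(0,),
        )
        assert res.folds.k == 4
        assert set(res.predictions["fold"].unique()) == {1, 2, 3, 4}
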