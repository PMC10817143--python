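"""norm.boot imputation, random-week assignment and Rubin's rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwgcharts.harmonize import (apply_eligibility, derive_subject_fields,
                                 derive_visit_fields)
from gwgcharts.imputation import (ImputationSpec, NormBootImputer, PMMImputer,
                                  assign_random_week,
                                  find_missing_first_trimester,
                                  impute_pipeline, rubin_pool)
from gwgcharts.synthetic import CohortConfig, generate_cohort


class TestFindMissing:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "ga_weeks",
                                           "weight_kg"])

    def test_window_boundary_inclusive(self):
        v = self._table([("a", 5, 50.0), ("a", 20, 55.0), ("b", 13, 52.0),
                         ("c", 14, 53.0), ("c", 30, 58.0)])
        missing = find_missing_first_trimester(v)
        assert missing == {"c"}

    def test_empty_table(self):
        assert find_missing_first_trimester(self._table([])) == set()

    def test_roster_includes_visitless_subjects(self):
        v = self._table([("a", 8, 50.0)])
        assert find_missing_first_trimester(v, subject_ids=["a", "z"]) == {"z"}


class TestAssignRandomWeek:
    def test_degenerate_window(self):
        got = assign_random_week(["a", "b"], window=(7, 7), seed=0)
        assert got == {"a": 7, "b": 7}

    def test_uniform_over_window(self):
        ids = [f"s{i}" for i in range(10000)]
        weeks = np.array(list(assign_random_week(ids, (5, 13), seed=3).values()))
        lo = stats.binom.ppf(0.0005, 10000, 1 / 9) / 10000   # ~99% multinomial
        hi = stats.binom.ppf(0.9995, 10000, 1 / 9) / 10000
        for w in range(5, 14):
            frac = (weeks == w).mean()
            assert lo <= frac <= hi

    def test_seed_and_order_stability(self):
        a = assign_random_week(["b", "a", "c"], seed=5)
        b = assign_random_week(["c", "b", "a"], seed=5)
        assert a == b


class TestNormBoot:
    def test_noiseless_linear_data_exact(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(5, 13, size=(60, 1))
        y = 40.0 + 0.5 * X[:, 0]
        imp = NormBootImputer(random_state=1).fit(X, y)
        X_mis = np.array([[6.0], [9.0], [12.5]])
        draws = imp.sample(X_mis, m=4)
        expected = 40.0 + 0.5 * X_mis[:, 0]
        for k in range(4):
            np.testing.assert_allclose(draws[k], expected, atol=1e-8)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(5, 13, size=(100, 1))
        y = 45 + 0.3 * X[:, 0] + rng.normal(0, 1, 100)
        d1 = NormBootImputer(random_state=7).fit(X, y).sample(X[:5], m=3)
        d2 = NormBootImputer(random_state=7).fit(X, y).sample(X[:5], m=3)
        np.testing.assert_array_equal(d1, d2)

    def test_unbiased_on_known_line(self):
        """|bias| < 0.15 kg over 50 replicates at n_obs = 2,000."""
        rng = np.random.default_rng(11)
        biases = []
        for _ in range(50):
            week = rng.integers(5, 14, size=2000).astype(float)
            y = 45.0 + 0.3 * week + rng.normal(0, 1, 2000)
            imp = NormBootImputer().fit(week[:, None], y)
            target_week = rng.integers(5, 14, size=200).astype(float)
            draws = imp.sample(target_week[:, None], m=1, rng=rng)
            truth = 45.0 + 0.3 * target_week
            biases.append(float(np.mean(draws[0] - truth)))
        assert abs(np.mean(biases)) < 0.15

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            NormBootImputer().fit(np.ones((2, 1)), np.array([1.0, 2.0]))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError):
            NormBootImputer().fit(X, np.arange(30.0))


class TestPMM:
    def test_imputed_values_are_observed_donors(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(5, 13, size=(80, 1))
        y = 45 + 0.3 * X[:, 0] + rng.normal(0, 1, 80)
        imp = PMMImputer(random_state=4, k=5).fit(X, y)
        draws = imp.sample(np.array([[6.0], [11.0]]), m=3)
        assert all(v in set(y) for v in draws.ravel())


class TestRubinPool:
    def test_no_between_variance(self):
        est = rubin_pool([10.0, 10.0, 10.0], [4.0, 4.0, 4.0])
        assert est.Qbar == 10.0 and est.B == 0.0 and est.T == 4.0
        assert np.isinf(est.df)

    def test_hand_computed_example(self):
        est = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert est.Qbar == pytest.approx(2.0)
        assert est.Ubar == pytest.approx(1.0)
        assert est.B == pytest.approx(1.0)
        assert est.T == pytest.approx(1.0 + (4.0 / 3.0))
        assert est.df == pytest.approx(2 * (1 + 1 / (4 / 3)) ** 2)

    def test_degenerate_zero(self):
        est = rubin_pool([0.0, 0.0], [0.0, 0.0])
        assert est.T == 0.0

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([1.0], [1.0])

    def test_total_variance_identity(self):
        rng = np.random.default_rng(8)
        Q = rng.normal(size=7)
        U = rng.uniform(0.1, 2.0, size=7)
        est = rubin_pool(Q, U)
        assert est.T == pytest.approx(est.Ubar + (1 + 1 / 7) * est.B)


@pytest.fixture(scope="module")
def clean_cohort(height_ref, bmi_ref):
    cfg = CohortConfig(n_sites=4, subjects_per_site=150, seed=19)
    subjects, visits, truth = generate_cohort(cfg)
    sd = derive_subject_fields(subjects, height_ref, bmi_ref)
    vd = derive_visit_fields(visits, sd)
    subj, vis, _ = apply_eligibility(sd, vd)
    return subj, vis


class TestImputePipeline:
    def test_all_categories_off_is_noop(self, clean_cohort):
        subj, vis = clean_cohort
        spec = ImputationSpec(categories=(), seed=1)
        completed, diag = impute_pipeline(subj, vis, spec)
        assert len(completed) == spec.m
        for cd in completed:
            assert not cd["imputed"].any()
            pd.testing.assert_frame_equal(
                cd.drop(columns=["imputed", "imputation"]),
                vis.reset_index(drop=True))
        assert not diag["imputed"].any()

    def test_observed_rows_identical_across_m(self, clean_cohort):
        subj, vis = clean_cohort
        completed, _ = impute_pipeline(subj, vis, ImputationSpec(seed=2))
        base = completed[0][~completed[0]["imputed"]].drop(columns="imputation")
        for cd in completed[1:]:
            other = cd[~cd["imputed"]].drop(columns="imputation")
            pd.testing.assert_frame_equal(base, other)

    def test_assigned_week_shared_across_m(self, clean_cohort):
        subj, vis = clean_cohort
        completed, _ = impute_pipeline(subj, vis, ImputationSpec(seed=2))
        weeks = [cd[cd["imputed"]].set_index("subject_id")["ga_weeks"]
                 for cd in completed]
        for w in weeks[1:]:
            pd.testing.assert_series_equal(weeks[0], w)
        assert weeks[0].between(5, 13).all()

    def test_imputed_only_for_missing_subjects(self, clean_cohort):
        subj, vis = clean_cohort
        completed, _ = impute_pipeline(subj, vis, ImputationSpec(seed=3))
        missing = find_missing_first_trimester(
            vis, subject_ids=subj["subject_id"])
        imputed_ids = set(completed[0].loc[completed[0]["imputed"],
                                           "subject_id"])
        assert imputed_ids <= missing

    def test_missing_fraction_diagnostic(self, height_ref, bmi_ref):
        """Raw-cohort missing fraction stays in the binomial band of 10%."""
        cfg = CohortConfig(n_sites=3, subjects_per_site=200, seed=23)
        subjects, visits, _ = generate_cohort(cfg)
        sd = derive_subject_fields(subjects, height_ref, bmi_ref)
        vd = derive_visit_fields(visits, sd)
        _, diag = impute_pipeline(sd, vd, ImputationSpec(seed=1))
        n = diag["n_subjects"].sum()
        frac = diag["n_missing_first_trimester"].sum() / n
        lo = stats.binom.ppf(0.005, n, 0.10) / n
        hi = stats.binom.ppf(0.995, n, 0.10) / n
        assert lo <= frac <= hi

    def test_determinism(self, clean_cohort):
        subj, vis = clean_cohort
        c1, _ = impute_pipeline(subj, vis, ImputationSpec(seed=9))
        c2, _ = impute_pipeline(subj, vis, ImputationSpec(seed=9))
        for a, b in zip(c1, c2):
            pd.testing.assert_frame_equal(a, b)

    def test_toggled_category_without_complete_cases_rejected(self):
        subjects = pd.DataFrame({
            "subject_id": ["a", "b"],
            "bmi_category": ["underweight", "underweight"],
            "prepreg_weight_kg": [50.0, 52.0]})
        visits = pd.DataFrame({"subject_id": ["a", "b"],
                               "ga_weeks": [20, 22],
                               "weight_kg": [55.0, 56.0],
                               "gwg_kg": [5.0, 4.0]})
        with pytest.raises(ValueError, match="no complete cases"):
            impute_pipeline(subjects, visits,
                            ImputationSpec(categories=("underweight",)))

    def test_envelope_with_subject_level_predictors(self, clean_cohort):
        """Imputed first-trimester GWG stays inside the observed envelope
        once the subject's pre-pregnancy weight anchors the prediction."""
        subj, vis = clean_cohort
        spec = ImputationSpec(
            seed=4, predictors=("assigned_week", "n_visits",
                                "prepreg_weight_kg"))
        completed, _ = impute_pipeline(subj, vis, spec)
        cat = subj.set_index("subject_id")["bmi_category"]
        allc = pd.concat(completed)
        for c in spec.categories:
            ids = set(cat.index[cat == c])
            obs = vis[vis["subject_id"].isin(ids)
                      & vis["ga_weeks"].between(5, 13)]["gwg_kg"].dropna()
            imp = allc[allc["imputed"]
                       & allc["subject_id"].isin(ids)]["gwg_kg"].dropna()
            # a handful of observed points is no envelope: require a
            # stable empirical range before asserting containment
            if len(obs) < 50 or len(imp) == 0:
                continue
            lo = obs.min() - 2 * obs.std()
            hi = obs.max() + 2 * obs.std()
            assert imp.between(lo, hi).all()


class TestCoverage:
    def test_rubin_interval_coverage_under_mnar(self):
        """95% Rubin intervals for the mean weight at week 9 cover >= 90%
        of the truth over 200 MNAR replicates (late-entry missingness)."""
        rng = np.random.default_rng(31)
        truth_at_9 = 45.0 + 0.3 * 9.0
        n, hits, reps = 1000, 0, 200
        for _ in range(reps):
            entry = rng.integers(5, 16, size=n)          # latent entry week
            week = np.maximum(rng.integers(5, 14, size=n), entry)
            observed = week <= 13                         # ~MNAR: late entry
            y = 45.0 + 0.3 * week + rng.normal(0, 1, n)
            imp = NormBootImputer().fit(week[observed, None].astype(float),
                                        y[observed])
            target = rng.integers(5, 14, size=(~observed).sum()).astype(float)
            draws = imp.sample(target[:, None], m=5, rng=rng)
            Qs, Us = [], []
            for k in range(5):
                yk = np.concatenate([y[observed], draws[k]])
                wk = np.concatenate([week[observed].astype(float), target])
                beta = np.polyfit(wk, yk, 1)
                resid = yk - np.polyval(beta, wk)
                pred_var = resid.var(ddof=2) * (
                    1 / len(yk) + (9 - wk.mean()) ** 2
                    / ((wk - wk.mean()) ** 2).sum())
                Qs.append(np.polyval(beta, 9.0))
                Us.append(pred_var)
            est = rubin_pool(Qs, Us)
            lo, hi = est.confint(0.95)
            hits += int(lo <= truth_at_9 <= hi)
        assert hits / reps >= 0.90
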