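"""Trajectory regression, FDR, partial correlations, pooled t tests."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

import nirsnet as nn
from nirsnet.stats import TERMS, canonical_term, fit_trajectory_table, trajectory_design


def make_cohort_arrays(rng, n_asd=77, n_td=40):
    n = n_asd + n_td
    age = rng.uniform(6, 16.6, n)
    is_asd = np.arange(n) < n_asd
    return age, is_asd


class TestDesign:
    def test_terms_canonicalized(self):
        assert canonical_term("age2:group") == "age2_group"
        assert canonical_term("age:group") == "age_group"
        with pytest.raises(ValueError):
            canonical_term("sex")

    def test_age_centered_and_squared(self, rng):
        age, is_asd = make_cohort_arrays(rng)
        d = trajectory_design(age, is_asd)
        assert d["age"].mean() == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(d["age2"], d["age"] ** 2)
        np.testing.assert_allclose(d["age_group"], d["age"] * is_asd)


class TestTrajectoryFit:
    def test_recovers_injected_raw_effect_with_vanishing_noise(self, rng):
        age, is_asd = make_cohort_arrays(rng)
        dz = trajectory_design(age, is_asd, standardize=True)
        y = 0.3 * dz["age2_group"].to_numpy() + rng.normal(0, 1e-8, len(age))
        fit = nn.fit_trajectory(y, age, is_asd)
        # with vanishing noise the outcome is perfectly explained: the raw
        # coefficient recovers the construction, the standardized one → 1
        sd_raw = trajectory_design(age, is_asd)["age2_group"].std(ddof=1)
        assert fit.beta_raw["age2_group"] == pytest.approx(0.3 / sd_raw, abs=1e-6)
        assert fit.beta_std["age2_group"] == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_recovers_injected_standardized_effect(self, rng):
        """Outcome built with a 0.3-SD age²:group component and unit total
        variance → standardized β5 ≈ 0.3 (averaged over replicates)."""
        age, is_asd = make_cohort_arrays(rng)
        dz = trajectory_design(age, is_asd, standardize=True)
        x5 = dz["age2_group"].to_numpy()
        betas = []
        for _ in range(30):
            y = 0.3 * x5 + np.sqrt(1 - 0.09) * rng.normal(size=len(age))
            betas.append(nn.fit_trajectory(y, age, is_asd).beta_std["age2_group"])
        assert np.mean(betas) == pytest.approx(0.3, abs=0.12)

    def test_subject_order_invariance(self, rng):
        age, is_asd = make_cohort_arrays(rng)
        y = rng.normal(size=len(age))
        fit = nn.fit_trajectory(y, age, is_asd)
        perm = rng.permutation(len(age))
        fit_p = nn.fit_trajectory(y[perm], age[perm], is_asd[perm])
        for t in TERMS:
            assert fit_p.beta_std[t] == pytest.approx(fit.beta_std[t])
            assert fit_p.pvalues[t] == pytest.approx(fit.pvalues[t])

    def test_standardized_and_raw_fits_share_t_and_p(self, rng):
        """z-scoring outcome and predictors must leave inference unchanged."""
        age, is_asd = make_cohort_arrays(rng)
        y = rng.normal(2.0, 0.5, len(age)) + 0.1 * (age - age.mean())
        fit = nn.fit_trajectory(y, age, is_asd)
        import statsmodels.api as sm

        dz = trajectory_design(age, is_asd, standardize=True)
        yz = (y - y.mean()) / y.std(ddof=1)
        ref = sm.OLS(yz, sm.add_constant(dz)).fit()
        for t in TERMS:
            assert fit.tvalues[t] == pytest.approx(float(ref.tvalues[t]), rel=1e-9)

    def test_type_one_error_near_nominal_under_null(self, rng):
        age, is_asd = make_cohort_arrays(rng)
        n_rep = 400
        Y = rng.normal(size=(len(age), n_rep))
        res = fit_trajectory_table(Y, age, is_asd)
        for it in range(5):
            rate = (res["p"][it] < 0.05).mean()
            assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_bulk_fit_matches_statsmodels(self, rng):
        age, is_asd = make_cohort_arrays(rng, 20, 15)
        Y = rng.normal(size=(35, 3))
        res = fit_trajectory_table(Y, age, is_asd)
        for j in range(3):
            fit = nn.fit_trajectory(Y[:, j], age, is_asd)
            for it, t in enumerate(TERMS):
                assert res["beta_std"][it, j] == pytest.approx(fit.beta_std[t], rel=1e-8)
                assert res["p"][it, j] == pytest.approx(fit.pvalues[t], rel=1e-8)
            assert res["r_squared"][j] == pytest.approx(fit.r_squared, rel=1e-8)

    def test_too_small_groups_rejected(self, rng):
        age, is_asd = make_cohort_arrays(rng, 12, 4)
        with pytest.raises(ValueError, match="per group"):
            nn.fit_trajectory(rng.normal(size=16), age, is_asd)


class TestFdr:
    def test_hand_worked_step_up(self):
        flags, _ = nn.fdr_correct([0.001, 0.04, 0.9], q=0.05)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_all_ones_nothing_significant(self):
        flags, _ = nn.fdr_correct(np.ones(10), q=0.05)
        assert not flags.any()

    def test_empty_input(self):
        flags, adj = nn.fdr_correct([], q=0.05)
        assert flags.size == 0 and adj.size == 0

    def test_matches_brute_force_step_up_on_random_vectors(self, rng):
        def bh_oracle(p, q):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            thresh = q * (np.arange(1, m + 1)) / m
            passed = np.flatnonzero(p[order] <= thresh)
            reject = np.zeros(m, dtype=bool)
            if passed.size:
                reject[order[: passed.max() + 1]] = True
            return reject

        for _ in range(1000):
            m = rng.integers(1, 60)
            p = rng.random(m)
            flags, _ = nn.fdr_correct(p, q=0.05)
            np.testing.assert_array_equal(flags, bh_oracle(p, 0.05))

    def test_false_discovery_proportion_controlled_under_null(self, rng):
        """BH at q=0.05 across 48 channels, fully null outcomes."""
        q = 0.05
        n_rep = 200
        age, is_asd = make_cohort_arrays(rng)
        fdp = np.zeros(n_rep)
        for rep in range(n_rep):
            Y = rng.normal(size=(len(age), 48))
            res = fit_trajectory_table(Y, age, is_asd)
            flags, _ = nn.fdr_correct(res["p"][TERMS.index("age2_group")], q=q)
            n_rej = flags.sum()
            fdp[rep] = 1.0 if n_rej > 0 else 0.0  # all discoveries are false
        mc_se = fdp.std(ddof=1) / np.sqrt(n_rep)
        assert fdp.mean() <= q + 2 * mc_se


class TestPartialCorrelation:
    def test_age_independent_identity(self, rng):
        x = rng.normal(size=50)
        age = rng.uniform(6, 16, 50)
        res = nn.partial_correlation(x, x, age)
        assert res.r == pytest.approx(1.0)

    def test_degenerate_pure_age_signals_flagged(self):
        age = np.linspace(6, 16, 30)
        x = 2.0 * age + 1.0
        y = -0.5 * age + 3.0
        res = nn.partial_correlation(x, y, age)
        assert res.undefined

    def test_matches_closed_form_three_variable_formula(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            x, y, c = rng.normal(size=(3, n))
            res = nn.partial_correlation(x, y, c)
            rxy = np.corrcoef(x, y)[0, 1]
            rxc = np.corrcoef(x, c)[0, 1]
            ryc = np.corrcoef(y, c)[0, 1]
            expected = (rxy - rxc * ryc) / np.sqrt((1 - rxc**2) * (1 - ryc**2))
            assert res.r == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        x, y, c = rng.normal(size=(3, 40))
        res = nn.partial_correlation(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ref = pg.partial_corr(df, x="x", y="y", covar="c")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestPooledTTest:
    def test_identical_groups_give_zero(self):
        cmp = nn.pooled_t_test(10, 5.0, 1.0, 12, 5.0, 1.0)
        assert cmp.t == 0.0 and cmp.p == pytest.approx(1.0)

    def test_viq_row_of_demographic_table(self):
        cmp = nn.pooled_t_test(77, 105.79, 17.44, 40, 106.05, 13.72)
        assert cmp.t == pytest.approx(-0.081, abs=0.002)
        assert cmp.df == 115

    def test_matches_scipy_on_random_summaries(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 50, 2)
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            cmp = nn.pooled_t_test(n1, m1, s1, n2, m2, s2)
            ref_t, ref_p = sps.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=True
            )
            assert cmp.t == pytest.approx(float(ref_t), rel=1e-10)
            assert cmp.p == pytest.approx(float(ref_p), rel=1e-10)

    def test_zero_variance_unequal_means_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            cmp = nn.pooled_t_test(5, 1.0, 0.0, 5, 2.0, 0.0)
        assert np.isinf(cmp.t) and cmp.p == 0.0

    def test_accepts_raw_samples(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        cmp = nn.pooled_t_test(sample1=a, sample2=b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=True)
        assert cmp.t == pytest.approx(float(ref_t))
        assert cmp.p == pytest.approx(float(ref_p))


class TestTidyAnalyses:
    @pytest.fixture()
    def tidy_inputs(self, rng):
        n = 40
        subjects = pd.DataFrame(
            {
                "subject_id": [f"S{i:03d}" for i in range(n)],
                "group": ["ASD"] * 25 + ["TD"] * 15,
                "age": rng.uniform(6, 16.6, n),
                "viq": rng.normal(105, 15, n),
                "piq": rng.normal(105, 15, n),
                "fsiq": rng.normal(103, 14, n),
                "ados_communication": list(rng.uniform(0, 8, 25)) + [np.nan] * 15,
                "ados_social": list(rng.uniform(0, 12, 25)) + [np.nan] * 15,
            }
        )
        rows = []
        for sid in subjects["subject_id"]:
            for ch in range(1, 7):
                rows.append(
                    {"subject_id": sid, "chromophore": "HbO", "metric": "degree",
                     "channel": ch, "auc": rng.normal(10, 2)}
                )
        return pd.DataFrame(rows), subjects

    def test_trajectory_analysis_shape_and_fdr_families(self, tidy_inputs):
        metrics, subjects = tidy_inputs
        out = nn.trajectory_analysis(metrics, subjects)
        assert len(out) == 6 * 5  # channels × terms
        assert set(out["term"]) == set(TERMS)
        assert out["p_fdr"].between(0, 1).all()

    def test_brain_behavior_restricted_to_asd(self, tidy_inputs):
        metrics, subjects = tidy_inputs
        out = nn.brain_behavior(metrics, subjects)
        assert (out["n"] == 25).all()
        assert len(out) == 6 * 2  # channels × two ADOS scales

    def test_demographics_table(self, tidy_inputs):
        _, subjects = tidy_inputs
        demo = nn.demographic_comparisons(subjects)
        assert list(demo["variable"]) == ["age", "viq", "piq", "fsiq"]
        assert demo["p"].between(0, 1).all()
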