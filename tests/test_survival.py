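"""Kaplan-Meier, stratified log-rank, Cox fits, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

import lbr12 as L
from lbr12.survival import concordance, stratified_logrank


def brute_force_concordance(risk, t, e):
    """Naive all-pairs Harrell's C: the oracle implementation."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and e[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


@pytest.fixture(scope="module")
def sim_report(sim_bundle):
    _, cohort, cls, _ = sim_bundle
    return L.compare_classifications(cohort.records, cls)


class TestKaplanMeier:
    def test_median_of_uncensored_sequence(self):
        km = L.km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert km.median == 3

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 200)
        km = L.km_estimate(t, np.ones(200, dtype=int))
        for time, s in zip(km.times[1:], km.survival[1:]):
            assert s == pytest.approx((t > time).mean())

    def test_all_censored_median_not_estimable(self):
        km = L.km_estimate([3, 5, 9], [0, 0, 0])
        assert math.isinf(km.median)
        assert km.median_label == "NE"

    def test_survival_starts_at_one_and_decreases(self, sim_bundle):
        _, cohort, _, _ = sim_bundle
        months = cohort.records["landmark_os_day"] / L.DAYS_PER_MONTH
        km = L.km_estimate(months, cohort.records["os_event"])
        assert km.survival[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.median_ci[0] <= km.median <= km.median_ci[1]


class TestStratifiedLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.tile([1.0, 2, 3, 4, 5], 2)
        e = np.tile([1, 0, 1, 1, 0], 2)
        g = np.repeat(["a", "b"], 5)
        res = stratified_logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_single_stratum_equals_plain_logrank(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(12, 300)
        e = rng.integers(0, 2, 300)
        g = rng.integers(0, 3, 300)
        mine = stratified_logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)
        explicit = stratified_logrank(t, e, g, strata=np.zeros(300))
        assert explicit.statistic == pytest.approx(mine.statistic, rel=1e-12)

    def test_detects_twofold_hazard_difference(self):
        rng = np.random.default_rng(9)
        n = 5000
        t = np.concatenate([rng.exponential(10, n), rng.exponential(5, n)])
        e = np.ones(2 * n, dtype=int)
        g = np.repeat([0, 1], n)
        res = stratified_logrank(t, e, g)
        assert res.p_value < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stratified_logrank([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_closed_form_two_subject_partial_likelihood(self):
        # times 1<2<3, all events, binary group (1,0,1): the partial
        # likelihood e^b/(2e^b+1) * 1/(e^b+1) is maximized at e^b = 1/sqrt(2)
        df = pd.DataFrame(
            {
                "landmark_months": [1.0, 2.0, 3.0],
                "os_event": [1, 1, 1],
                "grp": ["hi", "lo", "hi"],
            }
        )
        fit = L.fit_cox(df, "grp", "lo", covariates=(), strata_cols=())
        assert fit.hr("hi") == pytest.approx(2 ** -0.5, rel=1e-4)

    def test_identical_group_data_gives_unit_hazard_ratio(self):
        df = pd.DataFrame(
            {
                "landmark_months": [1.0, 2, 3, 4] * 2,
                "os_event": [1, 1, 0, 1] * 2,
                "grp": ["a"] * 4 + ["b"] * 4,
            }
        )
        fit = L.fit_cox(df, "grp", "a", covariates=(), strata_cols=())
        assert fit.hr("b") == pytest.approx(1.0, abs=1e-5)
        assert fit.lr_p > 0.99

    def test_recovers_twofold_hazard_ratio(self):
        rng = np.random.default_rng(42)
        n = 10_000
        df = pd.DataFrame(
            {
                "landmark_months": np.concatenate(
                    [rng.exponential(12, n), rng.exponential(6, n)]
                ),
                "os_event": 1,
                "grp": np.repeat(["ref", "fast"], n),
            }
        )
        fit = L.fit_cox(df, "grp", "ref", covariates=(), strata_cols=())
        assert 1.9 <= fit.hr("fast") <= 2.1

    def test_eventless_level_flagged_not_estimable(self):
        df = pd.DataFrame(
            {
                "landmark_months": [1.0, 2, 3, 4, 5, 6],
                "os_event": [1, 1, 1, 1, 0, 0],
                "grp": ["a", "a", "b", "b", "c", "c"],
            }
        )
        fit = L.fit_cox(df, "grp", "a", covariates=(), strata_cols=())
        row = fit.levels.set_index("level").loc["c"]
        assert not row["estimable"]
        assert np.isnan(row["hr"])

    def test_missing_covariates_dropped_and_counted(self, sim_bundle):
        _, cohort, cls, _ = sim_bundle
        df = cohort.records.merge(
            cls[["patient_id", "growth_pattern"]], on="patient_id"
        )
        df["landmark_months"] = df["landmark_os_day"] / L.DAYS_PER_MONTH
        fit = L.fit_cox(df, "growth_pattern", "SL_only")
        n_missing = df["ecog"].isna().sum()
        assert fit.n_dropped_missing == n_missing
        assert fit.n_used == len(df) - n_missing

    def test_replicate_log_hr_recovery_within_three_se(self):
        """Fitted pattern log-HRs track the generating exponential rates.

        Scaled-down replicate study: 8 cohorts of 3,000 patients; a
        replicate passes when every pattern's log-HR is within 3 SE of
        the generating value (ratio of configured median survivals).
        """
        passes = 0
        for rep in range(8):
            cfg = L.SimulationConfig(n_patients=3000, seed=500 + rep)
            lesions, patients, truth = L.simulate_cohort(cfg, return_patterns=True)
            df = patients.merge(truth, on="patient_id")
            df["landmark_months"] = (
                df["os_day"] - df["restaging_day"]
            ) / L.DAYS_PER_MONTH
            fit = L.fit_cox(
                df, "growth_pattern", "SL_only", covariates=(), strata_cols=()
            )
            med_ref = cfg.median_os_months[L.GrowthPattern.SL_ONLY]
            ok = True
            for _, row in fit.levels.iterrows():
                if row["level"] == "SL_only":
                    continue
                true_hr = med_ref / cfg.median_os_months[
                    L.GrowthPattern(row["level"])
                ]
                se = (math.log(row["ci_high"]) - math.log(row["ci_low"])) / (
                    2 * 1.959964
                )
                if abs(math.log(row["hr"]) - math.log(true_hr)) >= 3 * se:
                    ok = False
            passes += ok
        assert passes >= 7


class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        t = np.array([5.0, 4, 3, 2, 1])
        c, _ = concordance(-t, t, np.ones(5, dtype=int))
        assert c == 1.0

    def test_constant_predictor_gives_half(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 100)
        c, _ = concordance(np.zeros(100), t, np.ones(100, dtype=int))
        assert c == 0.5

    def test_matches_brute_force_and_sksurv(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(31)
        for _ in range(5):
            n = int(rng.integers(30, 150))
            t = rng.exponential(10, n)  # continuous: no tied times
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            risk = rng.normal(size=n).round(1)
            c, _ = concordance(risk, t, e)
            assert c == pytest.approx(brute_force_concordance(risk, t, e), abs=1e-12)
            sk = concordance_index_censored(e.astype(bool), t, risk)[0]
            assert c == pytest.approx(sk, abs=1e-12)

    def test_jackknife_ci_brackets_point(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(10, 300)
        e = rng.integers(0, 2, 300)
        e[0] = 1
        risk = -t + rng.normal(0, 5, 300)
        c, (lo, hi) = concordance(risk, t, e)
        assert lo < c < hi

    def test_bootstrap_ci_near_jackknife(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(10, 150)
        e = np.ones(150, dtype=int)
        risk = -t + rng.normal(0, 5, 150)
        c, (lo, hi) = concordance(risk, t, e, n_bootstrap=200, seed=7)
        assert lo < c < hi

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [3.0, 3.0], [1, 1])


class TestCompareClassifications:
    def test_lbr_concordance_at_least_recist(self, sim_report):
        """Within-SD heterogeneity gives the lesion-based criterion extra
        ordering information, so its concordance cannot fall below RECIST's."""
        tbl = sim_report["concordance_table"]
        overall = tbl[tbl["population"] == "overall"].iloc[0]
        assert overall["lbr12_concordance"] >= overall["recist_concordance"]

    def test_report_covers_all_populations(self, sim_report):
        assert sim_report["lbr12_overall"] is not None
        assert sim_report["recist_overall"] is not None
        assert set(sim_report["lbr12_by_regimen"]) == {
            "chemo_only", "VEGFi", "EGFRi", "VEGFi_and_EGFRi",
        }
        assert sim_report["prevalence"] is not None
        assert sim_report["within_recist"]["PR"].reference == "RL_only"
        assert sim_report["within_recist"]["SD"].reference == "RL_SL"

    def test_generative_hazard_ordering_recovered(self, sim_report):
        fit = sim_report["lbr12_overall"]
        assert fit.hr("RL_only") < 1 < fit.hr("SL_PL")
        assert fit.lr_p < 1e-10

    def test_identical_partitions_give_identical_concordance(self):
        """When no patient has a varied response, LBR12 is a relabeling of
        RECIST, so both systems rank patients identically."""
        probs = {p: 0.0 for p in L.GrowthPattern}
        probs[L.GrowthPattern.RL_ONLY] = 0.4
        probs[L.GrowthPattern.SL_ONLY] = 0.4
        probs[L.GrowthPattern.PL_ONLY] = 0.2
        cfg = L.SimulationConfig(
            n_patients=800, seed=55, pattern_probs=probs,
            disappearance_prob=0.0, complete_response_prob=0.0,
        )
        lesions, patients = L.simulate_cohort(cfg)
        cohort = L.build_analysis_cohort(lesions, patients)
        cls = L.classify_cohort(cohort, apply_5mm_rule=False)
        df = cohort.records.merge(
            cls[["patient_id", "growth_pattern", "recist"]], on="patient_id"
        )
        df["landmark_months"] = df["landmark_os_day"] / L.DAYS_PER_MONTH
        lb = L.fit_cox(df, "growth_pattern", "SL_only", covariates=(), strata_cols=())
        rc = L.fit_cox(df, "recist", "SD", covariates=(), strata_cols=())
        assert lb.concordance == pytest.approx(rc.concordance, abs=1e-12)

    def test_empty_sd_subset_skipped_with_warning(self):
        probs = {p: 0.0 for p in L.GrowthPattern}
        probs[L.GrowthPattern.RL_ONLY] = 0.5
        probs[L.GrowthPattern.PL_ONLY] = 0.5
        cfg = L.SimulationConfig(
            n_patients=300, seed=77, pattern_probs=probs,
            disappearance_prob=0.0, complete_response_prob=0.0,
        )
        lesions, patients = L.simulate_cohort(cfg)
        cohort = L.build_analysis_cohort(lesions, patients)
        cls = L.classify_cohort(cohort, apply_5mm_rule=False)
        with pytest.warns(UserWarning):
            report = L.compare_classifications(cohort.records, cls)
        assert report["within_recist"]["SD"] is None
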