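"""Clinical statistics: dichotomization boundary, prevalence rounding,
Kaplan-Meier product-limit, log-rank, the Cox fit against grid-search and
lifelines oracles, t-test, and the end-to-end cohort pipeline."""

import math

import numpy as np
import pytest

from tucrmir.simulate import CohortSimConfig, gen_cohort
from tucrmir.survival import (
    ConvergenceError,
    call_hypermethylated,
    cox_fit,
    enrichment_test,
    km_curve,
    logrank_test,
    prevalence,
    run_clinical_pipeline,
    ttest_unpaired,
)
from conftest import make_patient


class TestDichotomization:
    @pytest.mark.parametrize("beta,expected", [(0.34, True), (0.33, False), (0.0, False),
                                               (1.0, True), (0.3300001, True)])
    def test_strict_threshold(self, beta, expected):
        assert call_hypermethylated(beta) is expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            call_hypermethylated(1.2)


class TestPrevalence:
    def test_published_lgg_counts_round_to_one_decimal(self):
        cohort = [make_patient(f"c{i}", "LGG", 0.8 if i < 409 else 0.1) for i in range(503)]
        s = prevalence(cohort, "LGG")
        assert (s.n_total, s.n_hypermethylated) == (503, 409)
        assert s.pct_hypermethylated == 81.3

    def test_zero_prevalence(self):
        cohort = [make_patient(f"c{i}", "GBM", 0.1, grade="IV") for i in range(10)]
        assert prevalence(cohort, "GBM").pct_hypermethylated == 0.0

    def test_rounding_is_half_up(self):
        # 1/8 = 12.5% must round to 12.5; 3/16 = 18.75% must round to 18.8
        cohort = [make_patient(f"c{i}", "LGG", 0.9 if i < 3 else 0.1) for i in range(16)]
        assert prevalence(cohort).pct_hypermethylated == 18.8

    def test_planted_prevalence_counted(self):
        pats, truth = gen_cohort(CohortSimConfig(n_lgg=1000, n_gbm=134, prevalence_lgg=0.5), seed=8)
        s = prevalence(pats, "LGG")
        assert s.n_hypermethylated == truth["groups"]["LGG"]["n_hypermethylated"] == 500
        assert s.pct_hypermethylated == 50.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            prevalence([], "LGG")


class TestEnrichment:
    def test_planted_enrichment_significant(self):
        pats, _ = gen_cohort(seed=3)
        res = enrichment_test(pats)
        assert res.fisher_p < 1e-4
        assert res.table[0][0] == 409  # methylated LGG cases


class TestKaplanMeier:
    def test_four_uncensored_deaths(self):
        curve = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert curve.at_risk == [4, 3, 2, 1]

    def test_all_censored_flat(self):
        curve = km_curve([5, 10, 15], [0, 0, 0])
        assert curve.times == []  # no deaths, S stays at 1

    def test_mixed_toy_set_matches_hand_product(self):
        # deaths at 2 (5 at risk), 4 (3 at risk), 7 (1 at risk); censored at 3, 6
        times = [2, 3, 4, 6, 7]
        events = [1, 0, 1, 0, 1]
        curve = km_curve(times, events)
        assert curve.times == [2.0, 4.0, 7.0]
        s1 = 1 * (1 - 1 / 5)
        s2 = s1 * (1 - 1 / 3)
        s3 = s2 * (1 - 1 / 1)
        assert curve.survival == pytest.approx([s1, s2, s3])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(100, size=40).round(3)
        curve = km_curve(t, np.ones(40, dtype=int))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > time).mean())

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [5, 10, 15, 20]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_matches_hand_computation(self):
        # one death at t=1 in group A; both groups fully at risk (2 vs 2)
        chi2, p = logrank_test([1, 5], [1, 0], [5, 5], [0, 0])
        # O - E = 1 - 2/4 = 0.5; V = d*(n1*n2*(n-d))/(n^2*(n-1)) = 3/12 = 0.25
        assert chi2 == pytest.approx(0.5**2 / 0.25)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_null_type_i_error_within_three_se(self):
        rng = np.random.default_rng(42)
        n_reps, n = 1000, 40
        rejections = 0
        for _ in range(n_reps):
            ta = rng.exponential(100, n)
            tb = rng.exponential(100, n)
            ca = rng.uniform(0, 250, n)
            cb = rng.uniform(0, 250, n)
            chi2, p = logrank_test(
                np.minimum(ta, ca), (ta <= ca).astype(int),
                np.minimum(tb, cb), (tb <= cb).astype(int),
            )
            rejections += p < 0.05
        se = math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) <= 3 * se


def grid_search_cox(times, events, x, lo=-4.0, hi=4.0, step=1e-4):
    """Independent oracle: dense 1-D scan of the Breslow partial likelihood."""
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    events = np.asarray(events, int)
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for i, b in enumerate(betas):
        w = np.exp(b * x)
        total = 0.0
        for j in np.nonzero(events)[0]:
            risk = times >= times[j]
            total += b * x[j] - math.log(w[risk].sum())
        ll[i] = total
    return betas[int(np.argmax(ll))]


class TestCoxFit:
    def _toy(self, seed=0, n=24):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < 0.5).astype(float)
        h = 0.01 * 0.4**x
        t = rng.exponential(1 / h)
        t += rng.uniform(0, 1e-6, n)  # tie-free
        return t, np.ones(n, dtype=int), x

    def test_matches_grid_search_oracle(self):
        t, e, x = self._toy(seed=5)
        res = cox_fit(t, e, x)
        beta_grid = grid_search_cox(t, e, x)
        assert abs(res.coef[0] - beta_grid) < 1e-4

    def test_matches_lifelines_on_tie_free_data(self):
        # Breslow and Efron coincide without ties; lifelines is the cross-check
        import pandas as pd
        from lifelines import CoxPHFitter

        t, e, x = self._toy(seed=6, n=60)
        res = cox_fit(t, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), duration_col="t", event_col="e"
        )
        assert res.coef[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se[0] == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_efron_matches_lifelines_with_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 80
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(20, n))  # heavy ties
        e = (rng.random(n) < 0.7).astype(int)
        e[0] = 1
        res = cox_fit(t, e, x, ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), duration_col="t", event_col="e"
        )
        assert res.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(21)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(100, n)
        c = rng.uniform(0, 250, n)
        res = cox_fit(np.minimum(t, c), (t <= c).astype(int), x)
        assert 0.9 <= res.hr[0] <= 1.1

    def test_planted_hr_recovery_and_ci_coverage(self):
        # 500 cohort replicates with a protective planted hazard ratio of 0.5
        rng = np.random.default_rng(77)
        true_hr = 0.5
        hrs, covered = [], 0
        n_reps = 500
        for _ in range(n_reps):
            n = 600
            x = (rng.random(n) < 0.5).astype(float)
            h = 0.002 * true_hr**x
            t = rng.exponential(1 / h)
            c = rng.uniform(0, 1450, n)  # ~30% censoring
            res = cox_fit(np.minimum(t, c), (t <= c).astype(int), x)
            hrs.append(res.hr[0])
            covered += res.ci_low[0] <= true_hr <= res.ci_high[0]
        mc_se = np.std(hrs, ddof=1) / math.sqrt(n_reps)
        assert abs(np.mean(hrs) - true_hr) <= 3 * mc_se
        coverage = covered / n_reps
        assert abs(coverage - 0.95) <= 3 * math.sqrt(0.95 * 0.05 / n_reps)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1], np.ones(4))

    def test_complete_separation_detected(self):
        # perfect separation: all group-1 deaths precede every group-0 death
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        with pytest.raises((ConvergenceError, np.linalg.LinAlgError)):
            cox_fit(t, np.ones(8, dtype=int), x)


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_two_sample(self):
        a = [20.0, 22.0, 19.0, 20.0, 21.0]
        b = [28.0, 26.0, 27.0, 29.0, 25.0]
        t, p = ttest_unpaired(a, b)
        # pooled-variance formula by hand
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_hand)

    def test_zero_variance_equal_means_contract(self):
        assert ttest_unpaired([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(11)
        reps = 1000
        rej = sum(
            ttest_unpaired(rng.normal(size=20), rng.normal(size=20))[1] < 0.05
            for _ in range(reps)
        )
        assert abs(rej / reps - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)


class TestPipeline:
    def test_smoke_all_sections_finite(self):
        pats, _ = gen_cohort(seed=2)
        report = run_clinical_pipeline(pats)
        assert report["summaries"]["LGG"].pct_hypermethylated == 81.3
        assert 0 < report["enrichment"].fisher_p < 1e-4
        for name in ("all", "LGG", "GBM"):
            assert "logrank_p" in report["km_logrank"][name]
            assert np.isfinite(report["km_logrank"][name]["logrank_p"])
        uni = report["cox_univariate"]["LGG"]
        assert np.isfinite(uni["hypermethylated"]["hr"])
        multi = report["cox_multivariate_lgg"]
        assert set(multi) >= {"hypermethylated", "idh1_mut", "age", "sex_m"}

    def test_planted_protective_hr_covered_by_ci(self):
        planted = 0.135
        pats, _ = gen_cohort(CohortSimConfig(hr_methylation=planted), seed=17)
        report = run_clinical_pipeline(pats)
        uni = report["cox_univariate"]["LGG"]["hypermethylated"]
        assert uni["ci_low"] <= planted <= uni["ci_high"]

    def test_report_writer_emits_all_files(self, tmp_path):
        from tucrmir.survival import write_clinical_report

        pats, _ = gen_cohort(CohortSimConfig(n_lgg=150, n_gbm=60), seed=4)
        write_clinical_report(run_clinical_pipeline(pats), tmp_path)
        for name in ("summary.tsv", "enrichment.json", "km_LGG.tsv",
                     "cox_univariate.tsv", "cox_multivariate.tsv"):
            assert (tmp_path / name).exists()
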