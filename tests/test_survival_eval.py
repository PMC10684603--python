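"""Survival machinery against hand-computed and brute-force oracles:
Kaplan-Meier, log-rank, Aalen-Johansen, Gray's test, Cox partial
likelihood, Fine-Gray, concordance, time-dependent AUROC and grading AIC."""

import numpy as np
import pandas as pd
import pytest

from gvhdgrading import GeneratorConfig, generate_cohort
from gvhdgrading.simulate import severity_of
from gvhdgrading.survival import (
    cox_fit,
    cumulative_incidence,
    fine_gray_fit,
    grading_aic,
    gray_test,
    harrell_c,
    kaplan_meier,
    logrank_test,
    td_auroc,
)
from tests.conftest import make_cohort


def _uncensored_config(n, seed, **kw):
    """Study conditions with follow-up long enough that every event is
    observed (no censoring)."""
    return GeneratorConfig(
        n=n, seed=seed, dropout_rate=0.0, censoring_horizon=1e9,
        relapse_death_prob=1.0, **kw
    )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # deaths at 5, 8, 16; censored at 12 and 20
        rows = [
            ("a", 1, 0, 0, 5.0, "nrm", 1),
            ("b", 1, 0, 0, 8.0, "nrm", 1),
            ("c", 1, 0, 0, 12.0, "censored", 0),
            ("d", 1, 0, 0, 16.0, "nrm", 1),
            ("e", 1, 0, 0, 20.0, "censored", 0),
        ]
        curve = kaplan_meier(make_cohort(rows))[0]
        assert curve.at(5) == pytest.approx(4 / 5)
        assert curve.at(8) == pytest.approx(3 / 5)
        assert curve.at(15) == pytest.approx(3 / 5)
        assert curve.at(16) == pytest.approx(3 / 10)
        assert (curve.ci_lower <= curve.estimate + 1e-12).all()
        assert (curve.ci_upper >= curve.estimate - 1e-12).all()

    def test_all_censored_is_flat_one(self):
        rows = [(f"p{i}", 0, 0, 1, t, "censored", 0) for i, t in enumerate([3.0, 7.0, 9.0])]
        curve = kaplan_meier(make_cohort(rows))[0]
        assert np.all(curve.estimate == 1.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        cohort = generate_cohort(_uncensored_config(300, 21))
        curve = kaplan_meier(cohort)[0]
        times = cohort.times
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert curve.at(t) == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_duplicated_groups_null(self):
        rows = []
        for rep in range(2):
            for i, (t, e) in enumerate([(3, 1), (6, 0), (9, 1), (12, 1)]):
                rows.append((f"g{rep}p{i}", 1, 0, 0, float(t), "nrm" if e else "censored", e))
        cohort = make_cohort(rows)
        stat, df, p = logrank_test(cohort, [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_two_group_fixture_matches_oe_tally(self):
        data = [
            (3.0, 1, 0), (6.0, 0, 0), (9.0, 1, 0), (12.0, 1, 0),
            (2.0, 1, 1), (5.0, 1, 1), (8.0, 0, 1), (14.0, 0, 1),
        ]
        rows = [
            (f"p{i}", 1, 0, 0, t, "nrm" if e else "censored", e)
            for i, (t, e, _) in enumerate(data)
        ]
        cohort = make_cohort(rows)
        groups = [g for _, _, g in data]
        stat, df, p = logrank_test(cohort, groups)

        # direct observed-minus-expected tally with hypergeometric variance
        times = np.array([t for t, _, _ in data])
        events = np.array([e for _, e, _ in data])
        grp = np.array(groups)
        oe, var = 0.0, 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & (grp == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (grp == 1)).sum()
            oe += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx(oe**2 / var, rel=1e-9)
        assert df == 1

    def test_single_group_rejected(self, test_cohort):
        with pytest.raises(ValueError):
            logrank_test(test_cohort, [0] * len(test_cohort))


class TestCumulativeIncidence:
    def test_hand_aalen_johansen_with_competing_event(self):
        rows = [
            ("a", 0, 0, 2, 2.0, "nrm", 1),
            ("b", 0, 0, 2, 4.0, "relapse", 0),
            ("c", 0, 0, 2, 6.0, "nrm", 1),
            ("d", 0, 0, 2, 8.0, "censored", 0),
            ("e", 0, 0, 2, 10.0, "nrm", 1),
            ("f", 0, 0, 2, 12.0, "censored", 0),
        ]
        curve = cumulative_incidence(make_cohort(rows), "nrm")[0]
        assert curve.at(2) == pytest.approx(1 / 6)
        assert curve.at(5) == pytest.approx(1 / 6)
        assert curve.at(6) == pytest.approx(1 / 3)
        assert curve.at(10) == pytest.approx(7 / 12)

    def test_reduces_to_one_minus_km_without_competing_events(self):
        cohort = generate_cohort(
            GeneratorConfig(n=200, seed=8, baseline_hazard_relapse=1e-12)
        )
        cif = cumulative_incidence(cohort, "nrm")[0]
        km_df = pd.DataFrame({"t": cohort.times, "e": (cohort.event_codes == 1)})
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(km_df["t"], km_df["e"])
        for t in np.quantile(cohort.times, [0.25, 0.5, 0.75]):
            assert cif.at(t) == pytest.approx(1 - float(kmf.predict(t)), abs=1e-9)

    def test_cif_conservation_without_censoring(self):
        cohort = generate_cohort(_uncensored_config(150, 13))
        nrm = cumulative_incidence(cohort, "nrm")[0]
        rel = cumulative_incidence(cohort, "relapse")[0]
        times = cohort.times
        for t in np.quantile(times, [0.3, 0.6, 0.9]):
            surv = (times > t).mean()
            assert nrm.at(t) + rel.at(t) + surv == pytest.approx(1.0, abs=1e-9)
        assert all(nrm.at(t) + rel.at(t) <= 1 + 1e-9 for t in times)


class TestGray:
    def test_identical_duplicated_groups_null(self):
        base = [(2.0, "nrm", 1), (4.0, "relapse", 0), (6.0, "censored", 0), (8.0, "nrm", 1)]
        rows = [
            (f"g{rep}p{i}", 0, 0, 1, t, e, o)
            for rep in range(2)
            for i, (t, e, o) in enumerate(base)
        ]
        cohort = make_cohort(rows)
        stat, df, p = gray_test(cohort, "nrm", [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_label_swap_symmetric(self, test_cohort):
        labels = (test_cohort.df["gi"] >= 2).astype(int).to_numpy()
        a = gray_test(test_cohort, "nrm", labels)
        b = gray_test(test_cohort, "nrm", 1 - labels)
        assert a[0] == pytest.approx(b[0], rel=1e-9)

    def test_separates_severity_groups(self, test_cohort):
        labels = (severity_of(test_cohort.stage_matrix) > 2.0).astype(int)
        stat, df, p = gray_test(test_cohort, "nrm", labels)
        assert p < 1e-4

    def test_single_group_rejected(self, test_cohort):
        with pytest.raises(ValueError):
            gray_test(test_cohort, "nrm", np.zeros(len(test_cohort)))


class TestCox:
    def test_fixture_matches_grid_search_oracle(self):
        # 8 patients, distinct times, binary covariate
        data = [
            (1.0, 1, 1), (2.0, 1, 0), (3.0, 0, 1), (4.0, 1, 1),
            (5.0, 1, 0), (6.0, 0, 0), (7.0, 1, 1), (8.0, 0, 0),
        ]
        rows = [
            (f"p{i}", 1, 0, 0, t, "nrm" if e else "censored", e)
            for i, (t, e, _) in enumerate(data)
        ]
        cohort = make_cohort(rows)
        x = np.array([v for _, _, v in data], dtype=float)
        fit = cox_fit(cohort, x)

        def partial_loglik(beta):
            # written-out tie-free partial likelihood
            ll = 0.0
            times = np.array([t for t, _, _ in data])
            events = np.array([e for _, e, _ in data])
            for i in np.where(events == 1)[0]:
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.arange(-3, 3, 1e-3)
        values = [partial_loglik(b) for b in grid]
        best = grid[int(np.argmax(values))]
        assert float(fit.coefficients.iloc[0]) == pytest.approx(best, abs=2e-3)
        assert fit.loglik == pytest.approx(partial_loglik(float(fit.coefficients.iloc[0])), abs=1e-9)

    def test_efron_equals_breslow_on_tie_free_data(self):
        cohort = generate_cohort(GeneratorConfig(n=150, seed=14))
        x = severity_of(cohort.stage_matrix)
        assert len(np.unique(cohort.times[cohort.os_events == 1])) == int(
            cohort.os_events.sum()
        )
        efron = cox_fit(cohort, x)
        breslow = cox_fit(cohort, x, ties="breslow")
        assert efron.loglik == pytest.approx(breslow.loglik, abs=1e-8)
        assert float(efron.coefficients.iloc[0]) == pytest.approx(
            float(breslow.coefficients.iloc[0]), abs=1e-6
        )

    def test_agrees_with_lifelines_on_tied_data(self, test_cohort):
        x = severity_of(test_cohort.stage_matrix)
        fit = cox_fit(test_cohort, x)
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"t": test_cohort.times, "e": test_cohort.os_events, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert float(fit.coefficients.iloc[0]) == pytest.approx(
            float(cph.params_.iloc[0]), abs=1e-4
        )
        assert fit.loglik == pytest.approx(float(cph.log_likelihood_), abs=1e-4)

    def test_null_covariate_unbiased(self):
        hits = 0
        for rep in range(60):
            cohort = generate_cohort(GeneratorConfig(n=500, seed=3000 + rep))
            x = np.random.default_rng(rep).normal(size=500)
            fit = cox_fit(cohort, x)
            z = float(fit.coefficients.iloc[0] / fit.se.iloc[0])
            hits += abs(z) < 3
        assert hits >= 57  # >= 95% of reps

    def test_start_stop_intervals_supported(self, test_cohort):
        x = severity_of(test_cohort.stage_matrix)
        onset = np.minimum(20.0, test_cohort.times / 2)
        intervals = pd.DataFrame(
            {
                "start": onset,
                "stop": test_cohort.times,
                "event": test_cohort.os_events,
                "sev": x,
            }
        )
        fit = cox_fit(None, None, intervals=intervals)
        assert np.isfinite(fit.loglik)
        assert float(fit.coefficients.loc["sev"]) > 0

    def test_no_events_rejected(self):
        rows = [(f"p{i}", 1, 0, 0, 10.0, "censored", 0) for i in range(5)]
        with pytest.raises(ValueError, match="no events"):
            cox_fit(make_cohort(rows), np.arange(5.0))


def _finegray_truth_cohort(n, seed, beta=np.log(2.0), p=0.55, lam=0.001, cens=2500.0):
    """Direct draw from a Fine-Gray model with known subdistribution HR.

    F1(t | x) = 1 - (1 - p(1 - e^{-lam t}))^{exp(beta x)} for binary x.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    ehr = np.exp(beta * x)
    p_cause1 = 1 - (1 - p) ** ehr
    cause1 = rng.random(n) < p_cause1
    u = rng.random(n)
    t = np.empty(n)
    # invert F1(t|x)/F1(inf|x) for cause-1 subjects
    inner = (1 - (1 - u[cause1] * p_cause1[cause1]) ** (1 / ehr[cause1])) / p
    t[cause1] = -np.log(1 - inner) / lam
    t[~cause1] = rng.exponential(1 / (2 * lam), (~cause1).sum())
    c = rng.uniform(0, cens, n)
    time = np.minimum(t, c)
    event = np.where(t <= c, np.where(cause1, "nrm", "relapse"), "censored")
    rows = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "skin": 0,
            "liver": 0,
            "gi": 1,
            "time_days": time,
            "event": event,
            "os_event": (event == "nrm").astype(int),
        }
    )
    from gvhdgrading.cohort import CohortTable

    return CohortTable(rows), x


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        cohort = generate_cohort(
            GeneratorConfig(n=250, seed=9, baseline_hazard_relapse=1e-12)
        )
        x = severity_of(cohort.stage_matrix)
        fg = fine_gray_fit(cohort, x[:, None], "nrm")
        cs = cox_fit(cohort, x, outcome="nrm")
        assert float(fg.coefficients.iloc[0]) == pytest.approx(
            float(cs.coefficients.iloc[0]), abs=1e-3
        )

    def test_null_covariate_hr_near_one(self):
        cohort = generate_cohort(GeneratorConfig(n=400, seed=17))
        x = np.random.default_rng(17).normal(size=400)
        fg = fine_gray_fit(cohort, x[:, None], "nrm")
        coef, se = float(fg.coefficients.iloc[0]), float(fg.se.iloc[0])
        assert abs(coef) < 3 * se

    def test_recovers_known_subdistribution_hazard_ratio(self):
        estimates = []
        for rep in range(8):
            cohort, x = _finegray_truth_cohort(800, 500 + rep)
            fg = fine_gray_fit(cohort, x[:, None], "nrm")
            estimates.append(float(np.exp(fg.coefficients.iloc[0])))
        assert 1.6 <= float(np.median(estimates)) <= 2.5


class TestConcordance:
    def test_perfect_and_degenerate_scores(self):
        cohort = generate_cohort(_uncensored_config(100, 19))
        assert harrell_c(cohort, -cohort.times) == pytest.approx(1.0)
        assert harrell_c(cohort, np.zeros(100)) == pytest.approx(0.5)

    def test_matches_exhaustive_pair_oracle(self):
        data = [(2.0, 1, 3.0), (4.0, 1, 2.5), (5.0, 0, 1.0), (6.0, 1, 2.5), (8.0, 0, 0.5), (9.0, 1, 0.1)]
        rows = [
            (f"p{i}", 1, 0, 0, t, "nrm" if e else "censored", e)
            for i, (t, e, _) in enumerate(data)
        ]
        cohort = make_cohort(rows)
        scores = np.array([s for _, _, s in data])
        conc = disc = ties = 0
        for i in range(len(data)):
            for j in range(len(data)):
                ti, ei, si = data[i][0], data[i][1], scores[i]
                tj, _, sj = data[j][0], data[j][1], scores[j]
                if ei == 1 and ti < tj:  # i fails first, usable pair
                    if si > sj:
                        conc += 1
                    elif si < sj:
                        disc += 1
                    else:
                        ties += 1
        expected = (conc + 0.5 * ties) / (conc + disc + ties)
        assert harrell_c(cohort, scores) == pytest.approx(expected, abs=1e-12)

    def test_no_usable_pairs_flagged(self):
        rows = [(f"p{i}", 1, 0, 0, 10.0, "censored", 0) for i in range(4)]
        with pytest.warns(UserWarning, match="no usable pairs"):
            assert np.isnan(harrell_c(make_cohort(rows), np.arange(4.0)))


class TestTdAuroc:
    def test_perfect_separation_no_censoring(self):
        cohort = generate_cohort(_uncensored_config(150, 23))
        auc, _ = td_auroc(cohort, -cohort.times, horizon=365.0, n_bootstrap=20)
        assert auc == pytest.approx(1.0, abs=1e-9)

    def test_reduces_to_empirical_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        cohort = generate_cohort(_uncensored_config(400, 29))
        scores = severity_of(cohort.stage_matrix)
        auc, (lo, hi) = td_auroc(cohort, scores, horizon=365.0, n_bootstrap=30, seed=1)
        cases = cohort.times <= 365.0
        expected = roc_auc_score(cases, scores)
        assert auc == pytest.approx(expected, abs=1e-9)
        assert lo <= auc <= hi

    def test_independent_score_near_half(self):
        cohort = generate_cohort(GeneratorConfig(n=2000, seed=31))
        scores = np.random.default_rng(31).normal(size=2000)
        auc, _ = td_auroc(cohort, scores, horizon=365.0, n_bootstrap=10)
        assert auc == pytest.approx(0.5, abs=0.045)

    def test_horizon_beyond_followup_rejected(self, test_cohort):
        with pytest.raises(ValueError, match="horizon"):
            td_auroc(test_cohort, np.zeros(len(test_cohort)), horizon=1e9)


class TestGradingAic:
    def test_composition_with_cox_loglik(self, test_cohort, pc1_model):
        from gvhdgrading import grade_cohort

        grades = [a.grade for a in grade_cohort(test_cohort, "pc1", model=pc1_model)]
        aic = grading_aic(test_cohort, grades)
        dummies = pd.get_dummies(pd.Series(grades, dtype="category"), drop_first=True, dtype=float)
        loglik = cox_fit(test_cohort, dummies).loglik
        n_categories = len(set(grades))
        assert aic == pytest.approx(-2 * loglik + 2 * n_categories, abs=1e-9)
        # the conventional parameter count differs by exactly one category
        assert grading_aic(test_cohort, grades, p_convention="parameters") == pytest.approx(
            aic - 2, abs=1e-9
        )

    def test_single_category_rejected(self, test_cohort):
        with pytest.raises(ValueError, match="categories"):
            grading_aic(test_cohort, np.ones(len(test_cohort)))

    def test_informative_grading_beats_random_labels(self, test_cohort, pc1_model):
        from gvhdgrading import grade_cohort

        grades = [a.grade for a in grade_cohort(test_cohort, "pc1", model=pc1_model)]
        random_labels = np.random.default_rng(0).integers(1, 5, len(test_cohort))
        assert grading_aic(test_cohort, grades) < grading_aic(test_cohort, random_labels)
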