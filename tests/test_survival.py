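"""Log-rank, Cox regression, risk dichotomisation, LOO permutation test."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from protnet.errors import DomainError, InsufficientDataError
from protnet.survival import (
    cox_univariate,
    dichotomize_risk,
    km_logrank,
    loo_permutation_validate,
    rank_components_by_survival,
    risk_by_subtype,
)

from conftest import make_clinical, make_survival_data


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4, 5] * 2)
        e = np.array([True, True, False, True, False] * 2)
        lab = np.array(["A"] * 5 + ["B"] * 5)
        stat, p = km_logrank(t, e, lab)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_time_closed_form(self):
        # group A: 10 events at t=1; group B: 10 censored at t=2.
        # O-E = 10-5 = 5, V = 10*(1/2)*(1/2)*(10/19) = 25/19, chi2 = 19.
        t = np.array([1.0] * 10 + [2.0] * 10)
        e = np.array([True] * 10 + [False] * 10)
        lab = np.array(["A"] * 10 + ["B"] * 10)
        stat, p = km_logrank(t, e, lab)
        assert stat == pytest.approx(19.0, abs=1e-10)

    def test_matches_lifelines(self):
        for seed in range(5):
            t, e, x = make_survival_data(n=70, log_hr=0.5, seed=seed)
            g = x > np.median(x)
            stat, p = km_logrank(t, e, np.where(g, "hi", "lo"))
            ref = logrank_test(t[g], t[~g], e[g], e[~g])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-10)
            assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_tied_event_times_match_lifelines(self):
        rng = np.random.default_rng(8)
        t = np.round(rng.exponential(5, 60), 0) + 1
        e = rng.random(60) < 0.7
        g = rng.random(60) < 0.5
        stat, _ = km_logrank(t, e, np.where(g, "A", "B"))
        ref = logrank_test(t[g], t[~g], e[g], e[~g])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-10)

    def test_zero_events_raises(self):
        with pytest.raises(InsufficientDataError):
            km_logrank([1.0, 2.0], [False, False], ["A", "B"])


class TestCox:
    def test_constant_covariate(self):
        t, e, _ = make_survival_data(n=40, seed=0)
        res = cox_univariate(t, e, np.ones(40))
        assert res.coef == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_sign_with_negated_event_times(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 20)
        e = np.ones(20, bool)
        res = cox_univariate(t, e, -t)
        assert res.coef > 0  # earlier death <-> larger covariate

    def test_matches_lifelines_on_untied_data(self):
        for seed in range(4):
            t, e, x = make_survival_data(n=80, log_hr=0.8, seed=10 + seed)
            res = cox_univariate(t, e, x)
            cph = CoxPHFitter()
            cph.fit(
                pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
            assert res.coef == pytest.approx(cph.params_["x"], abs=1e-6)
            assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(60)
        t = np.round(rng.exponential(5 / np.exp(0.5 * x)), 0) + 1
        e = rng.random(60) < 0.8
        res = cox_univariate(t, e, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e")
        # lifelines' own stopping rule limits agreement on heavily tied data
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_parameter_recovery(self):
        # true log-HR 0.7 recovered within 0.1 in >= 90% of reps (n chosen so
        # the asymptotic se of the estimate is well below the 0.1 margin)
        hits = 0
        estimates = []
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(2000)
            T = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x)))
            res = cox_univariate(T, np.ones(2000, bool), x)
            estimates.append(res.coef)
            hits += abs(res.coef - 0.7) < 0.1
        assert hits / reps >= 0.9
        assert np.mean(estimates) == pytest.approx(0.7, abs=0.03)

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate drives |beta| to the bound
        t = np.arange(1.0, 21.0)
        e = np.ones(20, bool)
        x = -t  # perfect concordance
        res = cox_univariate(t, e, x)
        assert res.flagged

    def test_too_few_events_raises(self):
        with pytest.raises(InsufficientDataError):
            cox_univariate([1.0, 2.0], [True, False], [0.1, 0.2])


class TestDichotomize:
    def test_median_split(self):
        act = pd.Series(np.arange(1.0, 11.0), index=[f"S{i}" for i in range(10)])
        lab = dichotomize_risk(act, threshold_percentile=50, direction=1)
        assert (lab == "high").sum() == 5
        assert (lab == "low").sum() == 5

    def test_ties_at_cutoff_go_low(self):
        act = pd.Series([1.0] * 6, index=[f"S{i}" for i in range(6)])
        with pytest.raises(DomainError):
            dichotomize_risk(act, threshold_percentile=50, direction=1)
        act = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        lab = dichotomize_risk(act, threshold_percentile=50, direction=1)
        assert lab["c"] == "low"  # exactly at the median cutoff -> low
        assert (lab == "high").sum() == 2

    def test_negation_swaps_labels(self):
        rng = np.random.default_rng(2)
        act = pd.Series(rng.standard_normal(11), index=[f"S{i}" for i in range(11)])
        hi = dichotomize_risk(act, threshold_percentile=50, direction=1)
        lo = dichotomize_risk(-act, threshold_percentile=50, direction=-1)
        assert (hi == lo).all()


class TestLooPermutation:
    def _run(self, log_hr, seed, B=200, n=96):
        t, e, x = make_survival_data(n=n, log_hr=log_hr, seed=seed, censor_scale=30.0)
        clin = make_clinical(t, e)
        acts = pd.DataFrame([x], index=["Component 8"], columns=clin.sample_ids)
        return loo_permutation_validate(acts, clin, B=B, seed=seed)[0]

    def test_permutation_p_has_floor(self):
        res = self._run(log_hr=2.0, seed=0, B=100)
        assert res.permutation_p >= 1 / 101
        assert res.permutation_p == pytest.approx(1 / 101)

    def test_seed_reproducibility(self):
        a = self._run(log_hr=0.8, seed=3)
        b = self._run(log_hr=0.8, seed=3)
        assert a.permutation_p == b.permutation_p
        assert a.observed_statistic == b.observed_statistic
        assert (a.risk_labels == b.risk_labels).all()

    def test_strong_effect_significant(self):
        res = self._run(log_hr=1.5, seed=7)
        assert res.permutation_p <= 0.01
        assert res.hazard_ratio > 1.0

    def test_risk_table_shape(self):
        t, e, x = make_survival_data(n=60, log_hr=1.0, seed=5)
        subtypes = ["ER-true"] * 30 + ["TN-like"] * 15 + ["TNBC"] * 15
        clin = make_clinical(t, e, subtypes)
        acts = pd.DataFrame([x], index=["c"], columns=clin.sample_ids)
        res = loo_permutation_validate(acts, clin, B=100, seed=1)[0]
        tab = risk_by_subtype(res, clin)
        assert tab.shape == (3, 2)
        assert tab.sum().sum() == 60
        assert (tab.sum(axis=1) == pd.Series(
            {"ER-true": 30, "TN-like": 15, "TNBC": 15}
        )).all()

    def test_scan_mode_reports_best_percentile(self):
        res_scan = None
        t, e, x = make_survival_data(n=80, log_hr=1.2, seed=9, censor_scale=30.0)
        clin = make_clinical(t, e)
        acts = pd.DataFrame([x], index=["c"], columns=clin.sample_ids)
        res_scan = loo_permutation_validate(
            acts, clin, B=100, seed=2, scan=(30, 70, 10)
        )[0]
        assert res_scan.risk_threshold in {30.0, 40.0, 50.0, 60.0, 70.0}
        assert res_scan.permutation_p <= 0.05


class TestRanking:
    def test_single_component_rank_one(self):
        t, e, x = make_survival_data(n=50, log_hr=1.0, seed=0)
        clin = make_clinical(t, e)
        acts = pd.DataFrame([x], index=["only"], columns=clin.sample_ids)
        out = rank_components_by_survival(acts, clin)
        assert out.iloc[0]["rank"] == 1
        assert out.iloc[0]["component_id"] == "only"

    def test_duplicate_component_adjacent_ranks(self):
        t, e, x = make_survival_data(n=50, log_hr=1.0, seed=1)
        clin = make_clinical(t, e)
        acts = pd.DataFrame(
            [x, x], index=["a", "b"], columns=clin.sample_ids
        )
        out = rank_components_by_survival(acts, clin)
        assert out["km_logrank_p"].iloc[0] == out["km_logrank_p"].iloc[1]

    def test_prognostic_component_ranks_first(self):
        hits = 0
        reps = 25
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            t, e, x = make_survival_data(
                n=96, log_hr=1.2, seed=seed, censor_scale=30.0
            )
            clin = make_clinical(t, e)
            rows = [x] + [rng.standard_normal(96) for _ in range(8)]
            acts = pd.DataFrame(
                rows, index=["target"] + [f"null{i}" for i in range(8)],
                columns=clin.sample_ids,
            )
            out = rank_components_by_survival(acts, clin)
            hits += out.iloc[0]["component_id"] == "target"
        assert hits / reps >= 0.9
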