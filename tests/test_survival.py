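"""Survival stage: product-limit, log-rank and Cox against hand oracles,
maximally selected cutpoint against brute force."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

import fgfr_atlas as fa
from fgfr_atlas.survival import cox_univariate, cutpoint_permutation_p


def rec(i, t, e, c=0.0):
    return fa.SurvivalRecord(f"s{i}", float(t), bool(e), float(c))


class TestFilter:
    def test_thirty_day_inclusion_is_inclusive(self):
        records = [rec(0, 10, 1), rec(1, 30, 0), rec(2, 400, 1)]
        kept = fa.filter_survival(records, min_days=30)
        assert [r.time for r in kept] == [30, 400]

    def test_zero_threshold_keeps_all(self):
        records = [rec(0, 1, 1)]
        assert fa.filter_survival(records, 0) == records

    def test_empty_in_empty_out(self):
        assert fa.filter_survival([], 30) == []

    def test_nonpositive_time_rejected_at_construction(self):
        with pytest.raises(ValueError):
            rec(0, 0, 1)


class TestKaplanMeier:
    def test_two_events_no_censoring(self):
        curve = fa.km_estimate([rec(0, 1, 1), rec(1, 2, 1)])
        assert curve.at(1) == pytest.approx(0.5)
        assert curve.at(2) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = fa.km_estimate([rec(i, t, 0) for i, t in enumerate([1, 2, 3])])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit_with_intermediate_censoring(self):
        # events at 1 and 2, censoring at 1.5: S(1) = 2/3; at t=2 only one
        # subject remains at risk so S(2) = (2/3) * (1 - 1/1) = 0
        curve = fa.km_estimate([rec(0, 1, 1), rec(1, 1.5, 0), rec(2, 2, 1)])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2) == pytest.approx(0.0)

    def test_curve_starts_at_one_and_never_increases(self, record_factory):
        rng = np.random.default_rng(7)
        curve = fa.km_estimate(record_factory(rng, 50))
        assert curve.at(0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fa.km_estimate([])


def hand_logrank_chi2():
    """O-E table for A events at 1,2 vs B events at 3,4 (no censoring).

    t=1: n=4, nA=2, E=1/2, V=1/4;  t=2: n=3, nA=1, E=1/3, V=2/9;
    t=3, t=4: one group only, V=0.  O_A=2, E_A=5/6, V=17/36.
    chi2 = (7/6)^2 / (17/36) = 49/17.
    """
    return 49 / 17


class TestLogrank:
    def test_hand_o_minus_e_oracle(self):
        a = [rec(0, 1, 1), rec(1, 2, 1)]
        b = [rec(2, 3, 1), rec(3, 4, 1)]
        res = fa.logrank_test(a, b)
        assert res.chi2 == pytest.approx(hand_logrank_chi2())
        assert res.chi2 == pytest.approx(2.88, abs=0.01)

    def test_identical_groups_give_zero(self):
        g = [rec(0, 1, 1), rec(1, 5, 0), rec(2, 9, 1)]
        res = fa.logrank_test(g, list(g))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self, record_factory):
        rng = np.random.default_rng(11)
        a, b = record_factory(rng, 20), record_factory(rng, 25)
        assert fa.logrank_test(a, b).chi2 == pytest.approx(
            fa.logrank_test(b, a).chi2)

    def test_zero_events_degenerate(self):
        a, b = [rec(0, 1, 0)], [rec(1, 2, 0)]
        res = fa.logrank_test(a, b)
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agrees_with_lifelines(self, record_factory, seed):
        rng = np.random.default_rng(seed)
        a, b = record_factory(rng, 30), record_factory(rng, 35, hazard=0.02)
        res = fa.logrank_test(a, b)
        ref = ll_logrank(
            [r.time for r in a], [r.time for r in b],
            event_observed_A=[r.event for r in a],
            event_observed_B=[r.event for r in b],
        )
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_score_test_identity_on_tie_free_data(self, record_factory):
        # for two tie-free groups the Cox score statistic at beta=0 equals
        # the log-rank chi-square
        rng = np.random.default_rng(21)
        a = record_factory(rng, 15)
        b = record_factory(rng, 18, hazard=0.02)
        times = np.array([r.time for r in a + b])
        assert len(np.unique(times)) == len(times)
        event = np.array([r.event for r in a + b])
        x = np.array([1.0] * len(a) + [0.0] * len(b))
        u = info = 0.0
        for i in np.where(event)[0]:
            risk = times >= times[i]
            m = x[risk].mean()
            u += x[i] - m
            info += m - m**2
        assert fa.logrank_test(a, b).chi2 == pytest.approx(u**2 / info, abs=1e-6)


def brute_force_cutpoint(records, min_prop):
    """Independent maximizer: lifelines log-rank at every admissible threshold."""
    cov = np.array([r.covariate for r in records])
    best = None
    for c in np.unique(cov):
        high = cov >= c
        nh, nl = int(high.sum()), int((~high).sum())
        if min(nh, nl) == 0 or min(nh, nl) / len(records) < min_prop:
            continue
        res = ll_logrank(
            [r.time for r, h in zip(records, high) if h],
            [r.time for r, h in zip(records, high) if not h],
            event_observed_A=[r.event for r, h in zip(records, high) if h],
            event_observed_B=[r.event for r, h in zip(records, high) if not h],
        )
        if best is None or res.test_statistic > best[1] + 1e-12:
            best = (float(c), float(res.test_statistic))
    return best


class TestBestCutpoint:
    def test_matches_brute_force_on_random_records(self, record_factory):
        rng = np.random.default_rng(3)
        records = record_factory(rng, 30)
        result = fa.best_cutpoint(records, min_prop=0.1)
        cutoff, chi2 = brute_force_cutpoint(records, 0.1)
        assert result.cutoff == pytest.approx(cutoff)
        assert result.max_logrank_chi2 == pytest.approx(chi2, rel=1e-9)

    def test_returned_chi2_dominates_every_admissible_candidate(
            self, record_factory):
        rng = np.random.default_rng(17)
        records = record_factory(rng, 40)
        result = fa.best_cutpoint(records, min_prop=0.1)
        cov = np.array([r.covariate for r in records])
        for c in np.unique(cov):
            high = cov >= c
            if min(high.sum(), (~high).sum()) / len(records) < 0.1:
                continue
            lr = fa.logrank_test([r for r, h in zip(records, high) if h],
                                 [r for r, h in zip(records, high) if not h])
            assert result.max_logrank_chi2 >= lr.chi2 - 1e-9

    def test_planted_threshold_recovered(self):
        # hazard triples when the covariate crosses 0.5
        rng = np.random.default_rng(5)
        n = 200
        cov = rng.uniform(0, 1, n)
        hazard = np.where(cov >= 0.5, 0.03, 0.01)
        records = [rec(i, max(rng.exponential(1 / h), 1e-3), 1, c)
                   for i, (h, c) in enumerate(zip(hazard, cov))]
        result = fa.best_cutpoint(records, min_prop=0.1)
        assert abs(result.cutoff - 0.5) < 0.1

    def test_min_prop_excludes_thin_splits(self, record_factory):
        rng = np.random.default_rng(13)
        records = record_factory(rng, 50)
        result = fa.best_cutpoint(records, min_prop=0.1)
        assert min(result.n_low, result.n_high) >= 5
        cov = np.unique([r.covariate for r in records])
        admissible = sum(
            1 for c in cov
            if min((np.array([r.covariate for r in records]) >= c).sum(),
                   (np.array([r.covariate for r in records]) < c).sum()) >= 5
        )
        assert result.candidates_evaluated == admissible

    def test_too_small_cohort_errors(self):
        with pytest.raises(ValueError, match="too small"):
            fa.best_cutpoint([rec(0, 1, 1, 0.1)], min_prop=0.1)


def efron_grid_beta(records, group, lo=-3.0, hi=3.0, step=5e-5):
    """Grid-search maximizer of the Cox partial likelihood (tie-free data,
    binary covariate); independent of any fitting library."""
    times = np.array([r.time for r in records])
    event = np.array([r.event for r in records])
    x = np.asarray(group, float)
    betas = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(betas)
    ebx = np.exp(np.outer(betas, x))  # (n_beta, n)
    for i in np.where(event)[0]:
        risk = times >= times[i]
        ll += betas * x[i] - np.log(ebx[:, risk].sum(axis=1))
    return float(betas[np.argmax(ll)])


class TestCox:
    def test_newton_raphson_matches_grid_partial_likelihood(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(100, 8)
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        records = [rec(i, t, 1, int(g)) for i, (t, g) in
                   enumerate(zip(times, group))]
        fit = cox_univariate(records, group)
        oracle = efron_grid_beta(records, group)
        assert abs(fit.beta - oracle) < 1e-4

    def test_planted_log_hazard_ratio_recovered(self):
        m, a = fa.generate_cohort(
            fa.CohortSpec("BLCA", 500, 0,
                          survival_link=fa.SurvivalLink("FGFR1", 0.7),
                          censor_rate=0.2, seed=42))
        records = fa.build_survival_records(m, a, "FGFR1", "BLCA")
        z = np.log2([r.covariate for r in records])
        z = (z - z.mean()) / z.std()
        zrec = [fa.SurvivalRecord(r.sample_id, r.time, r.event, zv)
                for r, zv in zip(records, z)]
        # continuous-covariate fit via the same engine used for groups
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"T": [r.time for r in zrec],
                           "E": [int(r.event) for r in zrec],
                           "z": [r.covariate for r in zrec]})
        cph = CoxPHFitter().fit(df, "T", "E")
        beta = cph.summary.loc["z", "coef"]
        se = cph.summary.loc["z", "se(coef)"]
        assert abs(beta - 0.7) < 3 * se

    def test_null_coverage_of_wald_interval(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            times = rng.exponential(100, 200)
            event = rng.uniform(size=200) < 0.7
            group = np.arange(200) < 100
            records = [rec(i, t, e, int(g)) for i, (t, e, g) in
                       enumerate(zip(times, event, group))]
            fit = cox_univariate(records, group)
            if abs(fit.beta) < 3 * fit.se:
                hits += 1
        assert hits / n_seeds >= 0.93

    def test_no_events_in_high_group_gives_signed_sentinel(self):
        records = [rec(0, 1, 1, 0), rec(1, 2, 1, 0), rec(2, 3, 0, 1),
                   rec(3, 4, 0, 1)]
        fit = cox_univariate(records, [False, False, True, True])
        assert not fit.converged
        assert fit.beta == -np.inf and fit.hazard_ratio == 0.0

    def test_constant_group_errors(self):
        records = [rec(0, 1, 1, 0), rec(1, 2, 1, 0)]
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(records, [True, True])


class TestPermutationCorrection:
    def test_corrected_p_is_valid_and_not_smaller_than_naive(self,
                                                             record_factory):
        rng = np.random.default_rng(19)
        n = 40
        cov = rng.uniform(0, 1, n)
        hazard = np.where(cov >= 0.5, 0.05, 0.01)
        records = [rec(i, max(rng.exponential(1 / h), 1e-3), 1, c)
                   for i, (h, c) in enumerate(zip(hazard, cov))]
        cut = fa.best_cutpoint(records, 0.1)
        high = np.array([r.covariate >= cut.cutoff for r in records])
        naive = fa.logrank_test([r for r, h in zip(records, high) if h],
                                [r for r, h in zip(records, high) if not h])
        p_adj = cutpoint_permutation_p(records, 0.1, n_permutations=99, seed=1)
        assert 0 < p_adj <= 1
        assert p_adj >= naive.p_value


class TestSurvivalScan:
    def test_planted_adverse_effect_labeled_adverse(self, small_cohort):
        m, a = small_cohort
        scan = fa.survival_scan(m, a, ["FGFR1"])
        fit = scan.fits[0]
        assert fit.direction == "adverse"
        assert fit.hazard_ratio > 1
        assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high

    def test_constant_covariate_flagged(self, small_cohort):
        m, a = small_cohort
        const = pd.DataFrame(np.full((1, m.shape[1]), 7.0), index=["CONST"],
                             columns=m.samples)
        m2 = fa.ExpressionMatrix(pd.concat([m.data, const]))
        scan = fa.survival_scan(m2, a, ["CONST"])
        assert scan.fits == []
        assert scan.failed[0].reason == "constant covariate"

    def test_zero_event_cohort_flagged(self):
        m, a = fa.generate_cohort(
            fa.CohortSpec("BLCA", 30, 0, censor_rate=1.0, seed=2))
        scan = fa.survival_scan(m, a, ["FGFR1"])
        assert scan.fits == []
        assert scan.failed[0].reason == "no events"
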