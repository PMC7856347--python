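"""Tests for KM, log-rank, maxstat cut-points and the Cox hazard ratio."""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
import pandas as pd

from conftest import make_records
from endoscore import (ScoreTable, SimCohortConfig, SurvivalRecord, cox_hr,
                       km_estimate, logrank_scores, logrank_test,
                       maxstat_cutpoint, normalize_log, score_cohort,
                       simulate_cohort, stratify_and_analyze)


def random_cohort(rng, n, censor=0.3, groups=True):
    times = rng.exponential(1.0, size=n) + 1e-3
    events = (rng.random(n) > censor).astype(int)
    recs = make_records(times, events)
    grp = rng.random(n) < 0.5 if groups else None
    # ensure both groups have members and events
    if groups:
        grp[0], grp[1] = True, False
        events[:2] = 1
        recs = make_records(times, events)
    return recs, grp


class TestKaplanMeier:
    def test_three_events_no_censoring(self, toy_records):
        km = km_estimate(toy_records)
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_is_flat_one(self):
        km = km_estimate(make_records([1, 2, 5], [0, 0, 0]))
        assert km.times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_censoring_reduces_risk_set(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, S(3)=0
        km = km_estimate(make_records([1, 2, 3], [1, 0, 1]))
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 1]

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(2.0, size=40)
        km = km_estimate(make_records(times, np.ones(40, dtype=int)))
        for t in [0.5, 1.0, 2.0]:
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self, rng):
        recs, _ = random_cohort(rng, 60)
        km = km_estimate(recs)
        kmf = KaplanMeierFitter().fit([r.time for r in recs],
                                      [r.event for r in recs])
        ours = [km.survival_at(t) for t in km.times]
        theirs = [float(kmf.predict(t)) for t in km.times]
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalRecord("x", 0.0, 1)


class TestLogRank:
    def test_duplicated_groups_give_zero(self, toy_records):
        recs = toy_records + [SurvivalRecord(f"b{i}", r.time, r.event)
                              for i, r in enumerate(toy_records)]
        grp = np.array([True] * 3 + [False] * 3)
        res = logrank_test(recs, grp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_summed_table(self):
        # group A events at 1..4 all before group B events at 5..8
        recs = make_records([1, 2, 3, 4, 5, 6, 7, 8], [1] * 8)
        grp = np.array([True] * 4 + [False] * 4)
        o_minus_e, var = 0.0, 0.0
        n, n1 = 8, 4
        for t in range(1, 9):
            d1 = 1 if t <= 4 else 0
            o_minus_e += d1 - n1 / n
            var += (n1 / n) * (1 - n1 / n) * 1.0  # d=1, (n-d)/(n-1)=1
            n -= 1
            n1 -= d1
            if n1 < 0:
                n1 = 0
        expected = o_minus_e ** 2 / var
        res = logrank_test(recs, grp)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_matches_lifelines(self, rng):
        recs, grp = random_cohort(rng, 80)
        res = logrank_test(recs, grp)
        ll = ll_logrank([r.time for i, r in enumerate(recs) if grp[i]],
                        [r.time for i, r in enumerate(recs) if not grp[i]],
                        [r.event for i, r in enumerate(recs) if grp[i]],
                        [r.event for i, r in enumerate(recs) if not grp[i]])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_group_relabeling_invariance(self, rng):
        recs, grp = random_cohort(rng, 50)
        a = logrank_test(recs, grp)
        b = logrank_test(recs, ~grp)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_single_group_rejected(self, toy_records):
        with pytest.raises(ValueError, match="two non-empty groups"):
            logrank_test(toy_records, np.array([True, True, True]))

    def test_zero_events_rejected(self):
        recs = make_records([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="zero events"):
            logrank_test(recs, np.array([True, True, False, False]))


class TestLogrankScores:
    def test_scores_sum_to_zero_without_ties(self, rng):
        times = rng.exponential(1.0, size=30)
        events = (rng.random(30) > 0.3).astype(int)
        a = logrank_scores(make_records(times, events))
        assert a.sum() == pytest.approx(0.0, abs=1e-10)

    def test_early_event_scores_high(self):
        a = logrank_scores(make_records([1, 2, 3, 4], [1, 1, 1, 1]))
        assert np.all(np.diff(a) < 0)  # earlier events have larger scores


class TestMaxstat:
    def test_planted_split_is_found(self, rng):
        n = 60
        grp = np.arange(n) < n // 2
        rates = np.where(grp, 4.0, 1.0)
        times = rng.exponential(1.0 / rates)
        recs = make_records(times, np.ones(n, dtype=int))
        scores = grp + 0.01 * rng.random(n)  # two tight clusters at 0 and 1
        res = maxstat_cutpoint(scores, recs, n_permutations=500, seed=1)
        assert res.cutpoint < 1.0  # below the high cluster
        assert res.p_value <= 0.05
        assert res.n_high + res.n_low == n
        # the selected high group essentially recovers the planted group
        agreement = np.mean((scores > res.cutpoint) == grp)
        assert agreement >= 0.9

    def test_cutpoint_is_an_observed_value(self, rng):
        recs, _ = random_cohort(rng, 40)
        scores = rng.normal(size=40)
        res = maxstat_cutpoint(scores, recs, n_permutations=100, seed=0)
        assert res.cutpoint in scores
        assert res.p_value >= 1.0 / 101

    def test_no_candidate_window_rejected(self, rng):
        # minprop 0.45 with n=8 fails the n >= 10 gate first; use n=10 with
        # a window excluding every candidate
        recs, _ = random_cohort(rng, 10)
        scores = np.zeros(10)
        scores[:2] = 1.0
        with pytest.raises(ValueError, match="candidates|n >= 10"):
            maxstat_cutpoint(scores, recs, minprop=0.45, maxprop=0.55,
                             n_permutations=100, seed=0)

    def test_too_few_samples_rejected(self, rng):
        recs, _ = random_cohort(rng, 8)
        with pytest.raises(ValueError, match="n >= 10"):
            maxstat_cutpoint(np.arange(8.0), recs, n_permutations=100, seed=0)

    def test_deterministic_given_seed(self, rng):
        recs, _ = random_cohort(rng, 30)
        scores = rng.normal(size=30)
        a = maxstat_cutpoint(scores, recs, n_permutations=200, seed=7)
        b = maxstat_cutpoint(scores, recs, n_permutations=200, seed=7)
        assert a.cutpoint == b.cutpoint and a.p_value == b.p_value


class TestCox:
    def brute_partial_loglik(self, recs, grp, beta):
        """Independent Breslow partial log-likelihood."""
        total = 0.0
        for r, g in zip(recs, grp):
            if r.event == 1:
                risk = [float(gj) for rj, gj in zip(recs, grp) if rj.time >= r.time]
                total += beta * g - np.log(sum(np.exp(beta * x) for x in risk))
        return total

    def test_duplicated_groups_give_hr_one(self, toy_records):
        recs = toy_records + [SurvivalRecord(f"b{i}", r.time, r.event)
                              for i, r in enumerate(toy_records)]
        grp = np.array([True] * 3 + [False] * 3)
        res = cox_hr(recs, grp)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        recs = make_records([1.0, 1.5, 2.5, 3.0, 4.5, 6.0], [1, 1, 1, 0, 1, 1])
        grp = np.array([True, False, True, False, False, True])
        res = cox_hr(recs, grp)
        grid = np.linspace(-4, 4, 16001)
        lls = [self.brute_partial_loglik(recs, grp, b) for b in grid]
        assert res.log_hr == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        assert res.converged

    def test_matches_lifelines(self, rng):
        recs, grp = random_cohort(rng, 80)
        res = cox_hr(recs, grp)
        df = pd.DataFrame({"T": [r.time for r in recs],
                           "E": [r.event for r in recs],
                           "g": grp.astype(int)})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.log_hr == pytest.approx(float(cph.params_["g"]), abs=1e-5)
        assert res.se == pytest.approx(float(cph.standard_errors_["g"]), abs=1e-5)

    def test_score_test_at_zero_equals_logrank(self, rng):
        """With a binary covariate and no ties, U(0)^2 / I(0) is the
        log-rank chi-square."""
        for _ in range(5):
            recs, grp = random_cohort(rng, 40)
            t = np.array([r.time for r in recs])
            d = np.array([r.event for r in recs])
            u, info = 0.0, 0.0
            for ti in np.sort(t[d == 1]):
                at = t >= ti
                n1, n = int((at & grp).sum()), int(at.sum())
                x = grp[(t == ti) & (d == 1)][0]
                u += float(x) - n1 / n
                info += (n1 / n) * (1 - n1 / n)
            lr = logrank_test(recs, grp)
            assert u ** 2 / info == pytest.approx(lr.statistic, abs=1e-6)

    def test_separation_is_flagged_not_fatal(self):
        recs = make_records([1, 2, 3, 4, 10, 11, 12, 13], [1] * 8)
        grp = np.array([True] * 4 + [False] * 4)
        res = cox_hr(recs, grp)
        assert not res.converged
        assert np.isinf(res.log_hr) and res.log_hr > 0

    def test_event_in_each_group_required(self):
        recs = make_records([1, 2, 3, 4], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="event in each group"):
            cox_hr(recs, np.array([True, True, False, False]))

    def test_recovers_planted_hr(self):
        hrs = []
        for seed in range(15):
            _, recs, truth = simulate_cohort(
                SimCohortConfig(n_patients=300, planted_hr=3.0, seed=seed))
            grp = np.array([truth.labels[r.sample_id] == "high" for r in recs])
            hrs.append(cox_hr(recs, grp).hr)
        assert 2.4 <= np.median(hrs) <= 3.6


@pytest.fixture(scope="module")
def scored_cohort():
    matrix, records, truth = simulate_cohort(
        SimCohortConfig(n_patients=150, planted_hr=3.0, expression_lfc=1.0,
                        seed=17))
    table = score_cohort(normalize_log(matrix))
    return table, records, truth


class TestStratifyAndAnalyze:
    def test_end_to_end_detects_planted_risk(self, scored_cohort):
        table, records, _ = scored_cohort
        rep = stratify_and_analyze(table, records, n_permutations=300, seed=2)
        assert rep.cox.hr > 1.0
        assert rep.cox.p_value < 0.05
        assert rep.maxstat.n_high == len(rep.high_sample_ids)
        assert set(rep.high_sample_ids).isdisjoint(rep.low_sample_ids)

    def test_record_order_invariance(self, scored_cohort):
        table, records, _ = scored_cohort
        a = stratify_and_analyze(table, records, n_permutations=100, seed=4)
        shuffled = list(records)[::-1]
        b = stratify_and_analyze(table, shuffled, n_permutations=100, seed=4)
        assert a.maxstat.cutpoint == b.maxstat.cutpoint
        assert a.maxstat.p_value == b.maxstat.p_value
        assert a.cox.hr == pytest.approx(b.cox.hr, rel=1e-12)

    def test_difference_variant_recovers_risk_in_most_replicates(self):
        """The ratio statistic transmits only a sliver of the planted
        signal (its denominator pathology); the difference variant should
        recover the planted risk group in nearly every replicate."""
        successes = 0
        for seed in range(20):
            matrix, records, _ = simulate_cohort(SimCohortConfig(
                n_patients=300, planted_hr=3.0, expression_lfc=1.0, seed=seed))
            table = score_cohort(normalize_log(matrix), method="difference")
            rep = stratify_and_analyze(table, records, n_permutations=200,
                                       seed=seed)
            if rep.cox.hr > 1 and rep.cox.p_value < 0.05:
                successes += 1
        assert successes >= 18

    def test_no_overlapping_ids_rejected(self, scored_cohort):
        table, _, _ = scored_cohort
        strangers = make_records(np.arange(1, 21), np.ones(20, dtype=int),
                                 prefix="other")
        with pytest.raises(ValueError, match="both a score and a survival"):
            stratify_and_analyze(table, strangers, n_permutations=100, seed=0)


class TestMonotoneEffect:
    def test_median_hr_increases_with_planted_hr(self):
        medians = []
        for hr in (1.0, 2.0, 4.0):
            ests = []
            for seed in range(10):
                _, recs, truth = simulate_cohort(
                    SimCohortConfig(n_patients=250, planted_hr=hr, seed=100 + seed))
                grp = np.array([truth.labels[r.sample_id] == "high" for r in recs])
                ests.append(cox_hr(recs, grp).hr)
            medians.append(np.median(ests))
        assert medians[0] < medians[1] < medians[2]
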