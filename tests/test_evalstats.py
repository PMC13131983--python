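"""Time-dependent AUC, survival curves, log-rank, dichotomization."""

import numpy as np
import pytest
from scipy.stats import chi2

from vmap import evalstats
from vmap.errors import InputError, ThresholdError, UndefinedMetricError
from vmap.evalstats import (
    CENSORED,
    EVENT,
    EVENT_FREE,
    PRE,
    ablation_impact_analysis,
    auc_masks,
    classify,
    dichotomize,
    km_at,
    km_curve,
    logrank_test,
    risk_score,
    time_dependent_auc,
)


class TestRiskScore:
    def test_extremes(self):
        assert risk_score([1.0, 0, 0, 0], m=1) == 1.0
        assert risk_score([1.0, 0, 0, 0], m=2) == 1.0
        assert risk_score([0.0, 0, 0, 1.0], m=2) == 0.0

    def test_hand_summed_example(self):
        p = [0.2, 0.3, 0.1, 0.4]
        assert risk_score(p, m=1) == pytest.approx(0.5)
        assert risk_score(p, m=2) == pytest.approx(0.6)
        assert risk_score(p, m=1, mode="practice") == pytest.approx(0.2)

    def test_prognosis_score_nondecreasing_in_horizon(self, rng):
        p = rng.dirichlet(np.ones(8), size=20)
        scores = np.stack([risk_score(p, m) for m in range(1, 7)])
        assert np.all(np.diff(scores, axis=0) >= 0)
        with pytest.raises(InputError):
            risk_score(p, m=7)


def brute_force_auc(scores, status, bins, m):
    pos, neg = auc_masks(status, bins, m)
    total, count = 0.0, 0
    for sp in scores[pos]:
        for sn in scores[neg]:
            count += 1
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / count


class TestTimeDependentAuc:
    def test_trivial_cases(self):
        status = np.array([EVENT, EVENT, EVENT_FREE, EVENT_FREE])
        bins = np.array([1, 2, 0, 0])
        assert time_dependent_auc([0.9, 0.8, 0.1, 0.2], status, bins, 2) == 1.0
        assert time_dependent_auc([0.5] * 4, status, bins, 2) == 0.5

    def test_empty_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc([0.5, 0.6], [EVENT, EVENT], [1, 1], 1)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(100):
            n = 50
            scores = np.round(rng.uniform(0, 1, n), 2)  # force some ties
            status = rng.choice([PRE, EVENT, EVENT_FREE, CENSORED], size=n)
            bins = rng.integers(0, 7, size=n)
            bins[status == EVENT] = rng.integers(1, 7, size=(status == EVENT).sum())
            m = int(rng.integers(1, 7))
            pos, neg = auc_masks(status, bins, m)
            if pos.sum() == 0 or neg.sum() == 0:
                continue
            got = time_dependent_auc(scores, status, bins, m)
            assert got == pytest.approx(brute_force_auc(scores, status, bins, m), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        n = 80
        scores = rng.uniform(0, 1, n)
        status = rng.choice([PRE, EVENT, EVENT_FREE, CENSORED], size=n)
        bins = np.where(status == EVENT, rng.integers(1, 5, n), rng.integers(0, 5, n))
        a = time_dependent_auc(scores, status, bins, 4)
        b = time_dependent_auc(np.exp(3 * scores), status, bins, 4)
        assert a == pytest.approx(b, abs=1e-12)


class TestKaplanMeier:
    def test_no_censoring_is_one_minus_ecdf(self):
        times, surv = km_curve([1, 2, 3], [True, True, True])
        assert km_at([1, 2, 3], [1, 1, 1], 1) == pytest.approx(2 / 3)
        assert km_at([1, 2, 3], [1, 1, 1], 2) == pytest.approx(1 / 3)
        assert km_at([1, 2, 3], [1, 1, 1], 3) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        _, surv = km_curve([5, 10, 15], [False, False, False])
        assert np.all(surv == 1.0)

    def test_mixed_eight_subject_hand_table(self):
        # hand product-limit: d/n at t=1:1/8, t=2:1/7, t=3:1/5, t=5:1/3
        times = [1, 2, 2, 3, 4, 5, 6, 7]
        events = [1, 1, 0, 1, 0, 1, 0, 0]
        assert km_at(times, events, 1) == pytest.approx(7 / 8)
        assert km_at(times, events, 2) == pytest.approx(7 / 8 * 6 / 7)
        assert km_at(times, events, 3) == pytest.approx(7 / 8 * 6 / 7 * 4 / 5)
        assert km_at(times, events, 6) == pytest.approx(7 / 8 * 6 / 7 * 4 / 5 * 2 / 3)


class TestLogrank:
    def test_identical_groups_are_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_single_event_time(self):
        """All of A fails at day 1, B censored at 100: O-E=2.5, V=25/36."""
        stat, p = logrank_test([1] * 5, [1] * 5, [100] * 5, [0] * 5)
        d, n_a, n = 5, 5, 10
        e_a = d * n_a / n
        v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected = (5 - e_a) ** 2 / v
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(chi2.sf(expected, 1), rel=1e-9)

    def test_symmetry_under_group_swap(self, rng):
        ta, tb = rng.exponential(100, 20), rng.exponential(150, 25)
        ea, eb = rng.uniform(size=20) < 0.7, rng.uniform(size=25) < 0.7
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_requires_events_and_subjects(self):
        with pytest.raises(UndefinedMetricError):
            logrank_test([], [], [1], [1])
        with pytest.raises(UndefinedMetricError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestDichotomize:
    def test_separable_pair_returns_midpoint(self):
        scores = np.array([0.9, 0.1])
        status = np.array([EVENT, EVENT_FREE])
        bins = np.array([1, 0])
        theta = dichotomize(scores, status, bins, m=1)
        assert theta == pytest.approx(0.5)
        assert classify(0.6, theta) == "Incomplete"
        assert classify(0.4, theta) == "Complete"

    def test_identical_scores_raise(self):
        with pytest.raises(ThresholdError):
            dichotomize([0.5, 0.5, 0.5], [EVENT, PRE, EVENT_FREE], [1, 0, 0], m=1)

    def test_youden_matches_exhaustive_scan(self, rng):
        n = 100
        scores = rng.uniform(0, 1, n)
        status = rng.choice([PRE, EVENT, EVENT_FREE, CENSORED], size=n)
        bins = np.where(status == EVENT, rng.integers(1, 5, n), rng.integers(0, 5, n))
        theta = dichotomize(scores, status, bins, m=4)
        pos, neg = auc_masks(status, bins, 4)
        used = pos | neg

        def youden(t):
            called = scores[used] > t
            sens = (called & pos[used]).sum() / pos[used].sum()
            spec = (~called & ~pos[used]).sum() / (~pos[used]).sum()
            return sens + spec - 1

        grid = np.unique(scores[used])
        best = max(youden((a + b) / 2) for a, b in zip(grid[:-1], grid[1:]))
        assert youden(theta) == pytest.approx(best, rel=1e-12)


class TestImpactAnalysis:
    def test_eventless_stratum_is_reported_not_raised(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "pvi_event_day": [None, None, None, None],
                "bepvi_event_day": [None, None, None, None],
                "recurrence_day": [None, None, None, None],
                "followup_end_day": [400.0, 400.0, 400.0, 400.0],
                "additional_after": [True, False, True, False],
            }
        )
        inc = {"PVI": np.array([1, 1, 0, 0], bool), "bePVI": np.zeros(4, bool)}
        out = ablation_impact_analysis(df, inc)
        for task in ("PVI", "bePVI", "union"):
            for stratum in ("Incomplete", "Complete"):
                assert out[task][stratum]["logrank_p"] is None
                assert "reason" in out[task][stratum]

    def test_planted_benefit_in_incomplete_stratum(self, rng):
        """Additional ablation halves hazard only among incomplete maps."""
        import pandas as pd

        n = 400
        inc = rng.uniform(size=n) < 0.5
        add = rng.uniform(size=n) < 0.5
        rate = np.where(inc & ~add, 1 / 200.0, 1 / 800.0)
        t = rng.exponential(1 / rate)
        followup = 500.0
        event = t <= followup
        df = pd.DataFrame(
            {
                "pvi_event_day": np.where(event, t, np.nan),
                "bepvi_event_day": np.nan,
                "recurrence_day": np.where(event, t, np.nan),
                "followup_end_day": followup,
                "additional_after": add,
            }
        )
        out = ablation_impact_analysis(df, {"PVI": inc, "bePVI": np.zeros(n, bool)})
        entry = out["PVI"]["Incomplete"]
        assert entry["logrank_p"] < 0.05
        assert entry["km_1y_additional"] > entry["km_1y_no_additional"]
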