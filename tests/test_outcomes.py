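"""Survival and logistic machinery against brute-force oracles."""

import numpy as np
import pytest

from acnscore.outcomes import (EventDefinition, InsufficientDataError,
                               SurvivalSample, UndefinedTestError,
                               compare_scores, cox_fit, km_estimate, log_rank,
                               logistic_fit, mann_whitney_auc, outcome_event)
from acnscore.cohort import Outcome

from oracles import (auc_by_pair_counting, cox_breslow_loglik, cox_grid_mle,
                     km_by_risk_sets, logrank_by_risk_sets)


def samples_from(times, events, groups=None):
    groups = groups if groups is not None else ["a"] * len(times)
    return [SurvivalSample(t, bool(e), g)
            for t, e, g in zip(times, events, groups)]


def random_survival(rng, n, two_groups=True):
    times = np.round(rng.exponential(10, size=n), 2) + 0.1
    events = rng.random(n) < 0.7
    groups = (rng.choice(["a", "b"], size=n) if two_groups
              else np.array(["a"] * n))
    if two_groups:  # ensure both groups occupied
        groups[0], groups[1] = "a", "b"
    if not events.any():
        events[0] = True
    return times, events, groups


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(samples_from([3, 5, 8], [0, 0, 0]))
        assert np.allclose(curve.survival, 1.0)

    def test_three_events_closed_form(self):
        curve = km_estimate(samples_from([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            km_estimate([])

    def test_matches_risk_set_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            times, events, _ = random_survival(rng, n, two_groups=False)
            curve = km_estimate(samples_from(times, events))
            grid, surv = km_by_risk_sets(times, events)
            assert np.allclose(curve.times, grid)
            assert np.allclose(curve.survival, surv, atol=1e-10)

    def test_per_group_estimation(self):
        curves = km_estimate(
            samples_from([1, 2, 3, 4], [1, 1, 0, 0], ["a", "b", "a", "b"]),
            by_group=True)
        assert set(curves) == {"a", "b"}


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 0] * 2
        groups = ["a"] * 4 + ["b"] * 4
        result = log_rank(samples_from(times, events, groups))
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.df == 1

    def test_four_observation_hand_example(self):
        """A: events at 1, 2; B: events at 3, 4 - summed over 4 risk sets."""
        times, events, groups = [1, 2, 3, 4], [1, 1, 1, 1], list("AABB")
        result = log_rank(samples_from(times, events, groups))
        oracle = logrank_by_risk_sets(times, events, groups)
        assert result.chi2 == pytest.approx(oracle, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedTestError):
            log_rank(samples_from([1, 2], [0, 0], ["a", "b"]))

    def test_matches_risk_set_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            times, events, groups = random_survival(rng, n)
            result = log_rank(samples_from(times, events, groups))
            oracle = logrank_by_risk_sets(times, events, groups)
            assert result.chi2 == pytest.approx(oracle, abs=1e-10)


class TestCox:
    def test_aic_identity(self, rng):
        times, events, groups = random_survival(rng, 30)
        res = cox_fit(samples_from(times, events, groups))
        assert res.aic == pytest.approx(
            2 * len(res.params) - 2 * res.log_partial_likelihood, abs=1e-12)

    def test_partial_likelihood_matches_breslow_oracle(self, rng):
        """The model's log partial likelihood equals the explicit
        risk-set summation at arbitrary beta."""
        import statsmodels.api as sm
        for _ in range(30):
            n = int(rng.integers(4, 13))
            times, events, groups = random_survival(rng, n)
            x = (groups == "b").astype(float)
            model = sm.PHReg(times, x[:, None], status=events.astype(float),
                             ties="breslow")
            for beta in (-1.3, 0.0, 0.7, 2.1):
                assert model.loglike(np.array([beta])) == pytest.approx(
                    cox_breslow_loglik(beta, times, events, x), abs=1e-10)

    def test_estimate_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 13))
            times, events, groups = random_survival(rng, n)
            x = (groups == "b").astype(float)
            res = cox_fit(samples_from(times, events, groups), reference="a")
            if not res.converged:
                continue
            beta_grid, _ = cox_grid_mle(times, events, x)
            assert res.params["group[b]"] == pytest.approx(beta_grid, abs=1e-3)

    def test_two_observation_closed_form(self):
        """One event among two subjects: logPL(b) = -log(1 + exp(b dx));
        the likelihood is monotone, so the fit is flagged."""
        res = cox_fit(samples_from([1, 2], [1, 0], ["a", "b"]), reference="a")
        assert not res.converged

    def test_separation_is_flagged_not_fatal(self):
        samples = samples_from([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0],
                               ["b", "b", "b", "a", "a", "a"])
        res = cox_fit(samples, reference="a")
        assert not res.converged
        assert np.isfinite(res.aic)

    def test_constant_covariate_rejected(self):
        with pytest.raises(InsufficientDataError):
            cox_fit(samples_from([1, 2], [1, 0], ["a", "a"]))


class TestLogistic:
    def test_predictor_identical_to_outcome_has_auc_one(self):
        y = [True, True, False, False, True, False]
        res = logistic_fit(y, ["p" if v else "n" for v in y], reference="n")
        assert res.auc == pytest.approx(1.0)
        assert not res.converged  # complete separation, flagged

    def test_constant_predictor_has_auc_half(self):
        res = logistic_fit([True, False, True, False], ["x"] * 4)
        assert res.auc == pytest.approx(0.5)

    def test_binary_predictor_auc_closed_form(self, rng):
        """For a two-valued score, AUC = (sensitivity + specificity) / 2."""
        a, b, c, d = 12, 4, 6, 18   # TP, FN, FP, TN
        y = [True] * (a + b) + [False] * (c + d)
        pred = (["pos"] * a + ["neg"] * b + ["pos"] * c + ["neg"] * d)
        res = logistic_fit(y, pred, reference="neg")
        sens, spec = a / (a + b), d / (c + d)
        assert res.auc == pytest.approx((sens + spec) / 2, abs=1e-12)
        fitted = [res.params["intercept"] + (p == "pos") * res.params["group[pos]"]
                  for p in pred]
        assert res.auc == pytest.approx(auc_by_pair_counting(fitted, y),
                                        abs=1e-12)

    def test_constant_outcome_rejected(self):
        with pytest.raises(InsufficientDataError):
            logistic_fit([True, True], ["a", "b"])

    def test_auc_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        y = rng.random(40) < 0.4
        if not (y.any() and (~y).any()):
            y[0], y[1] = True, False
        base = mann_whitney_auc(scores, y)
        for transform in (np.exp, np.tanh, lambda s: 3 * s - 7):
            assert mann_whitney_auc(transform(scores), y) == pytest.approx(
                base, abs=1e-12)


class TestOutcomeCoding:
    def test_event_definitions(self):
        assert outcome_event(Outcome.DOD, EventDefinition.DOD) is True
        assert outcome_event(Outcome.AWD, EventDefinition.DOD) is False
        assert outcome_event(Outcome.AWD, EventDefinition.AWD_OR_DOD) is True
        assert outcome_event(Outcome.CR, EventDefinition.AWD_OR_DOD) is False
        assert outcome_event(Outcome.UNKNOWN, EventDefinition.DOD) is None


class TestCompareScores:
    def test_informative_system_ranks_first(self, rng):
        """A system whose classes track outcome beats an uninformative one
        on both AICs."""
        import pandas as pd
        n = 80
        outcome_is_bad = rng.random(n) < 0.4
        informative = np.where(outcome_is_bad & (rng.random(n) < 0.9),
                               "malignant", "benign")
        noise = rng.choice(["benign", "malignant"], size=n)
        times = np.where(outcome_is_bad, rng.exponential(12, n),
                         rng.exponential(200, n)) + 0.5
        panel = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(n)],
            "ara_class": informative,
            "pra_class": noise,
            "outcome": np.where(outcome_is_bad, "DOD", "CR"),
            "followup_months": np.round(times, 1),
        })
        cmp = compare_scores(panel, systems=("ara_class", "pra_class"))
        assert cmp.ranking[0] == "ara_class"
        assert (cmp.systems["ara_class"].logistic_aic
                < cmp.systems["pra_class"].logistic_aic)

    def test_single_system_comparison_is_trivial(self, rng):
        import pandas as pd
        n = 40
        bad = rng.random(n) < 0.5
        panel = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(n)],
            "pra_class": np.where(bad, "malignant", "benign"),
            "outcome": np.where(rng.random(n) < 0.3, "DOD", "CR"),
            "followup_months": np.round(rng.exponential(40, n) + 1, 1),
        })
        cmp = compare_scores(panel, systems=("pra_class",))
        assert cmp.ranking == ["pra_class"]

    def test_no_usable_subset_rejected(self):
        import pandas as pd
        panel = pd.DataFrame({
            "case_id": ["a", "b"],
            "pra_class": ["benign", "malignant"],
            "outcome": [None, None],
            "followup_months": [None, None],
        })
        with pytest.raises(InsufficientDataError):
            compare_scores(panel, systems=("pra_class",))
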