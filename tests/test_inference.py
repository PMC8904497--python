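import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ergochoice.betgen import BetCouple
from ergochoice.dynamics import Bet, Dynamic
from ergochoice.inference import (
    DegenerateComparisonError,
    PosteriorEstimate,
    SettingEstimate,
    aggregate,
    check_normality,
    compare_groups,
    estimate_couples,
    fit_couple,
    response_time_test,
    standardized_ranking,
)

ADD = Dynamic.ADDITIVE
MUL = Dynamic.MULTIPLICATIVE


class TestFitCouple:
    def test_closed_form_example(self, rng):
        est = fit_couple(30, 40, rng=rng)
        assert (est.alpha, est.beta_param) == (30.5, 10.5)
        assert est.mean == pytest.approx(30.5 / 41.0)
        a, b = 30.5, 10.5
        assert est.sd == pytest.approx(math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def test_no_data_returns_jeffreys_prior(self):
        with pytest.warns(UserWarning):
            est = fit_couple(0, 0)
        assert est.mean == 0.5
        assert (est.alpha, est.beta_param) == (0.5, 0.5)

    def test_split_and_order_invariance(self, rng):
        """Any 80/20 partition (and any split fraction) yields the same
        posterior as a single-shot conjugate update — asserted exactly."""
        for split in (0.0, 0.5, 0.8, 1.0):
            for _ in range(20):
                est = fit_couple(7, 25, split_fraction=split, rng=rng)
                assert (est.alpha, est.beta_param) == (7.5, 18.5)

    def test_conjugacy_sweep(self, rng):
        """Two-stage updating equals Beta(1/2+k, 1/2+n-k) for all k <= n <= 60."""
        for n in range(1, 61):
            for k in range(n + 1):
                est = fit_couple(k, n, rng=rng)
                assert (est.alpha, est.beta_param) == (0.5 + k, 0.5 + n - k)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fit_couple(5, 3)


class TestAggregate:
    def make(self, k, n, group="timed", setting=ADD, idx=1):
        return fit_couple(k, n, rng=np.random.default_rng(0), couple_index=idx, group=group, setting=setting)

    def test_single_estimate_passthrough(self):
        est = self.make(12, 20)
        agg = aggregate([est])
        assert agg.p_s == est.mean
        assert agg.sd_s == pytest.approx(est.sd)
        assert agg.m_couples == 1

    def test_identical_estimates_scale_like_standard_error(self):
        ests = [self.make(12, 20, idx=i) for i in range(9)]
        agg = aggregate(ests)
        assert agg.sd_s == pytest.approx(ests[0].sd / 3.0)

    def test_mean_within_bounds(self):
        ests = [self.make(k, 20, idx=k) for k in (2, 9, 17)]
        agg = aggregate(ests)
        means = [e.mean for e in ests]
        assert min(means) <= agg.p_s <= max(means)

    def test_mixed_settings_rejected(self):
        with pytest.raises(ValueError):
            aggregate([self.make(3, 10, setting=ADD), self.make(3, 10, setting=MUL)])

    def test_monte_carlo_propagation(self, rng):
        """Sampling each posterior and averaging draws reproduces (p_s, sd_s)."""
        ests = [self.make(k, 40, idx=k) for k in (10, 22, 31)]
        agg = aggregate(ests)
        n_mc = 200_000
        draws = np.mean(
            [rng.beta(e.alpha, e.beta_param, size=n_mc) for e in ests], axis=0
        )
        assert draws.mean() == pytest.approx(agg.p_s, abs=4 * agg.sd_s / math.sqrt(n_mc))
        assert draws.std(ddof=1) == pytest.approx(agg.sd_s, rel=0.02)


class TestGroupComparison:
    def make_setting(self, p, sd, group):
        return SettingEstimate(group=group, setting=MUL, p_s=p, sd_s=sd, m_couples=35)

    def test_identical_estimates_give_null_result(self):
        a = self.make_setting(0.55, 0.01, "timed")
        b = self.make_setting(0.55, 0.01, "control")
        comp = compare_groups(a, b)
        assert comp.z == 0.0
        assert comp.p_one_sided == 0.5

    def test_normal_cdf_example(self):
        comp = compare_groups(
            self.make_setting(0.60, 0.01, "timed"), self.make_setting(0.56, 0.01, "control")
        )
        assert comp.z == pytest.approx(4.0 / math.sqrt(2.0), rel=1e-12)
        assert comp.p_one_sided == pytest.approx(stats.norm.sf(4.0 / math.sqrt(2.0)), rel=1e-9)
        assert comp.p_one_sided == pytest.approx(0.00234, abs=5e-5)

    def test_zero_pooled_sd_degenerate(self):
        with pytest.raises(DegenerateComparisonError):
            compare_groups(self.make_setting(0.6, 0.0, "timed"), self.make_setting(0.5, 0.0, "control"))

    def test_mismatched_settings_rejected(self):
        a = self.make_setting(0.6, 0.01, "timed")
        b = SettingEstimate(group="control", setting=ADD, p_s=0.5, sd_s=0.01, m_couples=35)
        with pytest.raises(ValueError):
            compare_groups(a, b)


class TestNormalityCheck:
    def test_moderate_beta_posterior_is_near_normal(self):
        """Beta(30.5, 10.5) draws typically pass both normality tests; the
        U-shaped Jeffreys prior never does, at matched power."""
        est = PosteriorEstimate(alpha=30.5, beta_param=10.5, n=40, k=30)
        results = [
            check_normality(est, n_draws=200, rng=np.random.default_rng(s))
            for s in range(20)
        ]
        assert sum(r.shapiro_p > 0.05 for r in results) >= 10
        assert sum(r.jarque_bera_p > 0.05 for r in results) >= 10

    def test_jeffreys_prior_is_far_from_normal(self):
        est = PosteriorEstimate(alpha=0.5, beta_param=0.5, n=0, k=0)
        res = check_normality(est, n_draws=500, rng=np.random.default_rng(4))
        assert res.shapiro_p < 1e-6  # U-shaped density

    def test_reproducible_with_seed(self):
        est = PosteriorEstimate(alpha=10.5, beta_param=12.5, n=22, k=10)
        a = check_normality(est, rng=np.random.default_rng(8))
        b = check_normality(est, rng=np.random.default_rng(8))
        assert a == b

    def test_too_few_draws_rejected(self):
        est = PosteriorEstimate(alpha=1.0, beta_param=1.0, n=1, k=1)
        with pytest.raises(ValueError):
            check_normality(est, n_draws=10)


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p by enumeration of all group arrangements."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    n1n2 = n1 * len(y)
    lo = min(u_obs, n1n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = stats.mannwhitneyu(pooled[mask], pooled[~mask], alternative="two-sided").statistic
        total += 1
        if u <= lo or u >= n1n2 - lo:
            count += 1
    return count / total


class TestResponseTimeTest:
    def test_identical_samples_p_is_one(self):
        res = response_time_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_samples_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20 = 0.1."""
        res = response_time_test([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.median_timed == 2.0
        assert res.median_control == 5.0

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 2), (5, 4)])
    def test_agrees_with_permutation_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(loc=0.5, size=n2)
        res = response_time_test(x, y)
        assert res.p_value == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            response_time_test([1.0], [2.0, 3.0])


def ranking_fixture_table():
    """Two couples (one per setting) whose chosen bets are flip-independent."""
    couples = [
        BetCouple(1, ADD, riskier=Bet(-50, 50), safer=Bet(20, 20)),
        BetCouple(2, MUL, riskier=Bet(0.8, 1.25), safer=Bet(1.1, 1.1)),
    ]
    rows = []
    choices = {"P1": (1, 1), "P2": (1, 1), "P3": (0, 1)}
    for rid, (c1, c2) in choices.items():
        for idx, chose in ((1, c1), (2, c2)):
            rows.append(
                {
                    "respondent_id": rid,
                    "group": "timed",
                    "setting": couples[idx - 1].setting.value,
                    "couple_index": idx,
                    "chose_safer": chose,
                    "nobrainer_correct": pd.NA,
                    "response_time_s": 1.0,
                    "presentation_order": "safer_first",
                }
            )
    frame = pd.DataFrame(rows)
    frame["chose_safer"] = frame["chose_safer"].astype("Int64")
    frame["nobrainer_correct"] = frame["nobrainer_correct"].astype("boolean")
    return couples, frame


class TestStandardizedRanking:
    def test_hand_computed_capitals_and_tied_ranks(self):
        """Safer choices here are sure bets: capital = (1000 + 20) * 1.1 exactly;
        identical choices tie at the same capital and share rank 1."""
        couples, frame = ranking_fixture_table()
        table = standardized_ranking(frame, couples, coinflip_seed=0)
        caps = table.set_index("respondent_id")["final_capital"]
        assert caps["P1"] == pytest.approx(1020.0 * 1.1)
        assert caps["P2"] == pytest.approx(1020.0 * 1.1)
        # P3 took the risky additive bet: capital is (1000 ± 50) * 1.1
        assert caps["P3"] in (pytest.approx(950.0 * 1.1), pytest.approx(1050.0 * 1.1))
        ranks = table.set_index("respondent_id")["rank"]
        assert ranks["P1"] == ranks["P2"]  # identical choices tie exactly
        if caps["P3"] > caps["P1"]:
            assert ranks["P3"] == 1 and ranks["P1"] == 2
        else:
            assert ranks["P1"] == 1 and ranks["P3"] == 3

    def test_shared_coin_flips(self):
        """Respondents differing only in one choice differ exactly by the
        same drawn outcome — the flip is shared, not per respondent."""
        couples, frame = ranking_fixture_table()
        for seed in range(5):
            table = standardized_ranking(frame, couples, coinflip_seed=seed)
            caps = table.set_index("respondent_id")["final_capital"]
            diff = caps["P3"] / 1.1 - 1000.0
            assert diff == pytest.approx(-50.0) or diff == pytest.approx(50.0)

    def test_row_order_invariance(self):
        couples, frame = ranking_fixture_table()
        shuffled = frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = standardized_ranking(frame, couples, coinflip_seed=3)
        b = standardized_ranking(shuffled, couples, coinflip_seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_choices_rejected(self):
        couples, frame = ranking_fixture_table()
        with pytest.raises(ValueError):
            standardized_ranking(frame.iloc[:-1], couples, coinflip_seed=0)


class TestPipelineEstimation:
    def test_estimate_couples_counts_and_metadata(self, responses):
        ests = estimate_couples(responses, rng=np.random.default_rng(1))
        assert len(ests) == 2 * 2 * 35  # group x setting x scored couples
        for e in ests:
            assert e.alpha == 0.5 + e.k
            assert e.beta_param == 0.5 + e.n - e.k
            assert e.group in ("timed", "control")

    def test_credible_interval_brackets_mean(self):
        est = fit_couple(30, 40, rng=np.random.default_rng(0))
        lo, hi = est.credible_interval()
        assert lo < est.mean < hi
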