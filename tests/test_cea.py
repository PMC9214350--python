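import math
import random

import numpy as np
import pytest
from scipy import stats

from icerank.cea import (
    DominatedError,
    evaluate_arm,
    icer_interval,
    icer_point,
    monte_carlo_interval,
    rank_arms,
    round_display,
)
from icerank.core_model import (
    AggregateEffect,
    CostBasis,
    CostRecord,
    Domain,
    DomainName,
    EffectEstimate,
    InterventionArm,
    SchemeKind,
)


class TestRoundDisplay:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [
            (9.64, 0, 10),
            (2.35 / 3, 2, 0.78),
            (0.695, 2, 0.70),
            (99 / 0.40, 0, 248),   # 247.5: published convention is half-to-even
            (69 / 0.40, 0, 172),   # 172.5
            ((0.91 + 0.94) / 2, 2, 0.92),  # 0.925
            (0.755, 2, 0.76),
            (-0.5, 0, 0),
            (-1.5, 0, -2),
            (-0.51, 0, -1),
            (33924.999999999996, 0, 33925),
        ],
    )
    def test_cases(self, value, decimals, expected):
        assert round_display(value, decimals) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            round_display(math.inf)


class TestIcerPoint:
    def test_summed_three_domain_example(self):
        # cost 24 over summed benefit 2.49 displays as $10
        assert round_display(icer_point(24, 0, 2.49, 0)) == 10

    def test_zero_incremental_cost(self):
        assert icer_point(5, 5, 0.7, 0) == 0.0

    def test_hand_arithmetic(self):
        assert icer_point(100, 0, 0.5, 0) == 200.0

    def test_explicit_baseline(self):
        assert icer_point(150, 50, 1.0, 0.5) == pytest.approx(200.0)

    def test_dominated(self):
        with pytest.raises(DominatedError):
            icer_point(100, 0, 0.0, 0)
        with pytest.raises(DominatedError):
            icer_point(100, 0, 0.3, 0.5)


def agg(point, lower, upper, kind=SchemeKind.AVERAGED):
    return AggregateEffect(point, lower, upper, kind)


class TestIcerInterval:
    def test_three_domain_averaged_bounds(self):
        lower, upper = icer_interval(24, agg(0.83, 1.94 / 3, 3.10 / 3))
        assert (round_display(lower), round_display(upper)) == (23, 37)

    def test_wide_effect_interval(self):
        lower, upper = icer_interval(1357, agg(0.33, 0.04, 0.61))
        assert (round_display(lower), round_display(upper)) == (2225, 33925)

    def test_degenerate_interval_collapses(self):
        lower, upper = icer_interval(100, agg(0.5, 0.5, 0.5))
        assert lower == upper == pytest.approx(200.0)

    def test_nonpositive_lower_bound_unbounded(self):
        lower, upper = icer_interval(100, agg(0.2, -0.1, 0.5))
        assert math.isinf(upper)
        assert lower == pytest.approx(200.0)

    def test_nonpositive_upper_bound_dominated(self):
        with pytest.raises(DominatedError):
            icer_interval(100, agg(-0.3, -0.5, -0.1))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            icer_interval(-1, agg(0.5, 0.4, 0.6))


class TestEvaluateArm:
    def test_single_domain_arm_standardized(self, arms_by_id):
        arm = arms_by_id["nair_2009"]
        for kind in ("averaged", "summed"):
            r = evaluate_arm(arm, kind, "standardized")
            assert round_display(r.point) == 86
            assert round_display(r.lower) == 51
            assert round_display(r.upper) == 300

    def test_local_basis(self, arms_by_id):
        r = evaluate_arm(arms_by_id["yousafzai_2014"], "averaged", "local")
        assert round_display(r.point) == 206
        assert round_display(r.lower) == 177
        assert round_display(r.upper) == 298

    def test_unrounded_intermediates(self, arms_by_id):
        r = evaluate_arm(arms_by_id["powell_2004"], "averaged", "standardized")
        assert round_display(r.point) == 1647  # 1290/(2.35/3), not 1290/0.78

    def test_dominated_arm_flagged(self):
        arm = InterventionArm(
            arm_id="bad",
            study_label="s",
            country="c",
            study_year=2010,
            cost=CostRecord(per_child_local=10.0, per_child_standardized=10.0),
            effects=(EffectEstimate(Domain(DomainName.COGNITIVE), -0.2, -0.4, -0.1),),
        )
        r = evaluate_arm(arm, "averaged", "local")
        assert r.dominated
        assert math.isnan(r.point)

    def test_dominated_iff_nonpositive_point(self, paper_arms):
        for arm in paper_arms:
            r = evaluate_arm(arm, "summed", "local")
            assert r.dominated == (r.effect.point <= 0)


class TestRankArms:
    def test_fixture_ranking_averaged_standardized(self, eligible_arms):
        results = [evaluate_arm(a, "averaged", "standardized") for a in eligible_arms]
        table = rank_arms(results)
        assert table.rows[0].arm_id == "aboud_2013_home"
        assert table.rows[0].rank == 1
        assert table.rows[-1].arm_id == "lozoff_2010"
        assert table.rows[-1].rank == 12
        assert [r.rank for r in table.rows] == list(range(1, 13))

    def test_order_independence(self, eligible_arms):
        results = [evaluate_arm(a, "averaged", "standardized") for a in eligible_arms]
        baseline = rank_arms(results)
        rng = random.Random(11)
        for _ in range(3):
            rng.shuffle(results)
            assert rank_arms(results) == baseline

    def test_tie_break_cost_then_arm_id(self):
        def result(arm_id, cost):
            benefit = agg(0.5, 0.4, 0.6)
            return evaluate_arm(
                InterventionArm(
                    arm_id=arm_id,
                    study_label=arm_id,
                    country="c",
                    study_year=2010,
                    cost=CostRecord(per_child_local=cost, per_child_standardized=cost),
                    effects=(
                        EffectEstimate(Domain(DomainName.COGNITIVE), 0.5, 0.4, 0.6),
                    ),
                ),
                "averaged",
                "local",
            )

        # b and a share ICER and cost: lexicographic arm_id decides
        table = rank_arms([result("b", 10.0), result("a", 10.0)])
        assert [r.arm_id for r in table.rows] == ["a", "b"]
        # equal ICER, different cost: cheaper arm first
        r_cheap = evaluate_arm(
            InterventionArm(
                arm_id="z",
                study_label="z",
                country="c",
                study_year=2010,
                cost=CostRecord(per_child_local=5.0, per_child_standardized=5.0),
                effects=(EffectEstimate(Domain(DomainName.COGNITIVE), 0.25, 0.2, 0.3),),
            ),
            "averaged",
            "local",
        )
        table = rank_arms([result("a", 10.0), r_cheap])
        assert [r.arm_id for r in table.rows] == ["z", "a"]

    def test_mixed_scheme_or_basis_rejected(self, arms_by_id):
        arm = arms_by_id["nair_2009"]
        with pytest.raises(ValueError, match="mixed"):
            rank_arms(
                [
                    evaluate_arm(arm, "averaged", "standardized"),
                    evaluate_arm(arm, "summed", "standardized"),
                ]
            )

    def test_empty_input(self):
        table = rank_arms([])
        assert table.rows == ()

    def test_cost_monotonicity(self):
        benefit = agg(0.5, 0.4, 0.6)
        icers = [icer_point(c, 0, benefit.point, 0) for c in (10, 20, 40, 80)]
        assert icers == sorted(icers)
        assert len(set(icers)) == 4


def single_domain_arm(cost=100.0, estimate=0.5, se=0.1):
    return InterventionArm(
        arm_id="mc",
        study_label="mc",
        country="c",
        study_year=2010,
        cost=CostRecord(per_child_local=cost, per_child_standardized=cost),
        effects=(
            EffectEstimate(
                Domain(DomainName.COGNITIVE),
                estimate,
                estimate - 1.96 * se,
                estimate + 1.96 * se,
            ),
        ),
    )


class TestMonteCarlo:
    def test_seed_required(self, arms_by_id):
        with pytest.raises(ValueError, match="seed"):
            monte_carlo_interval(arms_by_id["nair_2009"], "averaged", "standardized")

    def test_deterministic_under_seed(self, arms_by_id):
        arm = arms_by_id["jin_2007"]
        a = monte_carlo_interval(arm, "summed", "standardized", 2000, seed=42)
        b = monte_carlo_interval(arm, "summed", "standardized", 2000, seed=42)
        assert a == b

    def test_degenerate_collapses_to_point(self):
        arm = single_domain_arm(cost=100.0, estimate=0.5, se=0.0)
        mc = monte_carlo_interval(arm, "averaged", "local", 1000, seed=1)
        assert mc.lower == mc.upper == pytest.approx(200.0)
        assert mc.n_nonpositive == 0

    def test_matches_closed_form_for_single_domain(self):
        # oracle: ICER percentiles = cost / opposite normal quantiles
        cost, d, se = 120.0, 0.8, 0.1
        arm = single_domain_arm(cost, d, se)
        mc = monte_carlo_interval(arm, "averaged", "local", 40_000, seed=7)
        q_low, q_high = stats.norm.ppf([0.025, 0.975], loc=d, scale=se)
        assert mc.lower == pytest.approx(cost / q_high, rel=0.02)
        assert mc.upper == pytest.approx(cost / q_low, rel=0.02)

    def test_nonpositive_draws_counted(self):
        arm = single_domain_arm(cost=50.0, estimate=0.05, se=0.5)
        mc = monte_carlo_interval(arm, "averaged", "local", 4000, seed=3)
        expected_share = stats.norm.cdf(0, loc=0.05, scale=0.5)
        assert mc.n_nonpositive / mc.n_samples == pytest.approx(expected_share, abs=0.05)

    def test_small_sample_rejected(self, arms_by_id):
        with pytest.raises(ValueError, match="n_samples"):
            monte_carlo_interval(arms_by_id["nair_2009"], "averaged", "local", 10, seed=1)


class TestGoldenLeague:
    def test_full_reproduction(self):
        from icerank.golden import compare_league

        report = compare_league()
        assert report.ok, [str(d) for d in report.diffs]
        assert report.n_icers == 48
        assert report.n_bounds == 96
        assert report.n_ranks == 48

    def test_perturbed_cost_flags_only_affected_cells(self, paper_arms):
        import dataclasses

        from icerank.golden import compare_league

        perturbed = []
        for arm in paper_arms:
            if arm.arm_id == "nair_2009":
                cost = dataclasses.replace(
                    arm.cost,
                    per_child_standardized=arm.cost.per_child_standardized + 1,
                )
                arm = dataclasses.replace(arm, cost=cost)
            perturbed.append(arm)
        report = compare_league(arms=perturbed)
        assert not report.ok
        assert {d.arm_id for d in report.diffs} == {"nair_2009"}
        assert all(d.basis == "standardized" for d in report.diffs)
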