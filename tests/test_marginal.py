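"""Cost-neutral portfolio feasibility, exhaustive enumeration, votes, decisions."""

import numpy as np
import pytest

from pbma.errors import SizeError, ValidationError
from pbma.marginal import (
    Ballotbox,
    Portfolio,
    ProgramComponent,
    Registry,
    apply_decision_rule,
    enumerate_feasible,
    portfolio_feasible,
    residual_after_recommendation,
    tally_votes,
)


def _component(cid, kind, cost, score=0.0, group=None):
    return ProgramComponent(
        id=cid,
        name=cid,
        kind=kind,
        cost_gbp_m=cost,
        currently_provided=(kind == "disinvestment"),
        final_score=score,
        exclusion_group=group,
    )


class TestProgramComponent:
    def test_investment_cannot_be_currently_provided(self):
        with pytest.raises(ValidationError):
            ProgramComponent("x", "x", "investment", 1.0, currently_provided=True)

    def test_disinvestment_must_be_currently_provided(self):
        with pytest.raises(ValidationError):
            ProgramComponent("x", "x", "disinvestment", 1.0, currently_provided=False)

    def test_divisible_flag_warns(self):
        with pytest.warns(UserWarning, match="divisible"):
            ProgramComponent("x", "x", "investment", 1.0, False, divisible=True)


class TestPortfolioFeasible:
    def test_case_study_hand_arithmetic(self, registry):
        p = Portfolio(
            frozenset({"care_homes"}),
            frozenset({"adult_orthodontics", "moderate_orthodontics"}),
        )
        feasible, residual = portfolio_feasible(p, registry)
        assert feasible and residual == pytest.approx(42.0)  # 11 + 44 - 13

    def test_empty_portfolio_is_feasible_with_zero_residual(self, registry):
        assert portfolio_feasible(Portfolio(), registry) == (True, 0.0)

    def test_cbt_unaffordable_even_disinvesting_everything(self, registry):
        every_current = frozenset(c.id for c in registry.disinvestments)
        p = Portfolio(frozenset({"cbt"}), every_current)
        feasible, residual = portfolio_feasible(p, registry)
        assert not feasible and residual == pytest.approx(592.0 - 824.0)

    def test_unknown_component_rejected(self, registry):
        with pytest.raises(ValidationError):
            portfolio_feasible(Portfolio(frozenset({"nope"})), registry)

    def test_wrong_kind_selection_rejected(self, registry):
        with pytest.raises(ValidationError):
            portfolio_feasible(Portfolio(frozenset({"routine_scaling"})), registry)

    def test_residual_additive_over_disjoint_selections(self, registry):
        a = Portfolio(frozenset({"care_homes"}), frozenset({"adult_orthodontics"}))
        b = Portfolio(frozenset({"dph_input"}), frozenset({"routine_scaling"}))
        union = Portfolio(
            a.selected_investments | b.selected_investments,
            a.selected_disinvestments | b.selected_disinvestments,
        )
        _, ra = portfolio_feasible(a, registry)
        _, rb = portfolio_feasible(b, registry)
        _, ru = portfolio_feasible(union, registry)
        assert ru == pytest.approx(ra + rb)

    def test_efficiency_release_adds_to_budget(self, registry):
        p = Portfolio(frozenset({"new_practices"}), frozenset(), efficiency_release_gbp_m=140.0)
        feasible, residual = portfolio_feasible(p, registry)
        assert feasible and residual == pytest.approx(5.0)


def _backtracking_feasible(investments, disinvestments, release):
    """Independent recursive oracle: all feasible (invest, disinvest) index sets."""
    results = []

    def recurse(i, inv, dis):
        if i == len(investments) + len(disinvestments):
            spent = sum(investments[j][1] for j in inv)
            freed = sum(disinvestments[j][1] for j in dis) + release
            if freed >= spent:
                results.append((frozenset(inv), frozenset(dis)))
            return
        if i < len(investments):
            recurse(i + 1, inv, dis)
            recurse(i + 1, inv | {i}, dis)
        else:
            j = i - len(investments)
            recurse(i + 1, inv, dis)
            recurse(i + 1, inv, dis | {j})

    recurse(0, frozenset(), frozenset())
    return set(results)


class TestEnumerateFeasible:
    def test_unaffordable_investment_never_appears(self):
        registry = Registry(
            [_component("big", "investment", 100.0), _component("cut", "disinvestment", 10.0)]
        )
        for portfolio, _ in enumerate_feasible(registry):
            assert "big" not in portfolio.selected_investments

    def test_two_investments_cannot_share_one_small_release(self):
        registry = Registry(
            [
                _component("i1", "investment", 10.0),
                _component("i2", "investment", 10.0),
                _component("d1", "disinvestment", 10.0),
            ]
        )
        for portfolio, _ in enumerate_feasible(registry):
            assert not (
                {"i1", "i2"} <= portfolio.selected_investments
            )

    def test_case_study_preventive_and_cbt_infeasible(self, registry):
        feasible = enumerate_feasible(registry, efficiency_release_gbp_m=0.0)
        assert feasible  # the scan finds plenty of feasible portfolios
        for portfolio, _ in feasible:
            assert "preventive_sessions" not in portfolio.selected_investments
            assert "cbt" not in portfolio.selected_investments

    def test_emitted_portfolios_agree_with_feasibility_check(self, registry):
        for portfolio, residual in enumerate_feasible(registry, 25.0):
            feasible, check = portfolio_feasible(portfolio, registry)
            assert feasible and check == pytest.approx(residual)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_recursive_backtracking_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_inv, n_dis = 5, 5
        inv = [(f"i{k}", float(rng.integers(1, 40))) for k in range(n_inv)]
        dis = [(f"d{k}", float(rng.integers(1, 40))) for k in range(n_dis)]
        release = float(rng.integers(0, 20))
        registry = Registry(
            [_component(c, "investment", cost) for c, cost in inv]
            + [_component(c, "disinvestment", cost) for c, cost in dis]
        )
        got = {
            (p.selected_investments, p.selected_disinvestments)
            for p, _ in enumerate_feasible(registry, release)
        }
        expected = {
            (
                frozenset(inv[j][0] for j in inv_idx),
                frozenset(dis[j][0] for j in dis_idx),
            )
            for inv_idx, dis_idx in _backtracking_feasible(inv, dis, release)
        }
        assert got == expected

    def test_exclusion_group_members_never_coselected(self):
        registry = Registry(
            [
                _component("orthoA", "disinvestment", 10.0, group="ortho"),
                _component("orthoB", "disinvestment", 20.0, group="ortho"),
            ]
        )
        for portfolio, _ in enumerate_feasible(registry):
            assert len(portfolio.selected_disinvestments) <= 1

    def test_pareto_filter_keeps_undominated_portfolios(self):
        registry = Registry(
            [
                _component("good", "investment", 5.0, score=1.5),
                _component("bad", "investment", 5.0, score=-1.5),
                _component("cut", "disinvestment", 10.0, score=-0.5),
            ]
        )
        kept = enumerate_feasible(registry, pareto_only=True)
        for portfolio, _ in kept:
            assert "bad" not in portfolio.selected_investments

    def test_oversized_registry_rejected(self):
        registry = Registry(
            [_component(f"i{k}", "investment", 1.0) for k in range(26)]
        )
        with pytest.raises(SizeError, match="26"):
            enumerate_feasible(registry)


class TestTallyVotes:
    def test_unanimous_and_empty_tallies(self, registry):
        everything = Portfolio(
            frozenset(c.id for c in registry.investments), frozenset()
        )
        box = tally_votes([everything] * 9, registry)
        assert box.votes_for_funding["care_homes"] == 9
        assert box.votes_for_funding["out_of_hours_pain"] == 9  # retained = funded
        nothing = Portfolio(frozenset(), frozenset(c.id for c in registry.disinvestments))
        box = tally_votes([nothing] * 9, registry)
        assert box.votes_for_funding["care_homes"] == 0
        assert box.votes_for_funding["out_of_hours_pain"] == 0

    def test_retention_semantics_for_current_services(self, registry):
        keep = Portfolio(frozenset(), frozenset())
        drop = Portfolio(frozenset(), frozenset({"molar_endodontics"}))
        box = tally_votes([keep] * 6 + [drop] * 3, registry)
        assert box.votes_for_funding["molar_endodontics"] == 6

    def test_infeasible_ballot_counted_but_logged(self, registry, caplog):
        overspend = Portfolio(frozenset({"cbt"}), frozenset())
        with caplog.at_level("WARNING", logger="pbma.marginal"):
            box = tally_votes([overspend], registry)
        assert box.votes_for_funding["cbt"] == 1
        assert "infeasible" in caplog.text


class TestDecisionRule:
    def test_case_study_spot_decisions(self, registry, ballotbox):
        rec = apply_decision_rule(ballotbox, registry, threshold=6)
        assert rec.decisions["care_homes"] == "Invest"  # 8 of 9, new
        assert rec.decisions["routine_scaling"] == "Disinvest"  # 2 of 9, current
        assert rec.decisions["homeless_care"] == "No investment"  # 5 of 9, new

    def test_tie_at_threshold_is_funded(self, registry, ballotbox):
        rec = apply_decision_rule(ballotbox, registry, threshold=6)
        assert rec.decisions["helpline_link"] == "Invest"  # exactly 6 votes
        assert rec.decisions["molar_endodontics"] == "Continue"  # exactly 6 votes

    def test_raising_threshold_only_shrinks_the_funded_set(self, registry, ballotbox):
        funded_sets = []
        for threshold in range(1, 10):
            rec = apply_decision_rule(ballotbox, registry, threshold=threshold)
            funded_sets.append(
                {c for c, d in rec.decisions.items() if d in ("Invest", "Continue")}
            )
        for lower, higher in zip(funded_sets, funded_sets[1:]):
            assert higher <= lower

    def test_sub_majority_threshold_warns(self, registry, ballotbox):
        with pytest.warns(UserWarning, match="majority"):
            apply_decision_rule(ballotbox, registry, threshold=2)

    def test_component_missing_from_box_rejected(self, registry):
        box = Ballotbox({"care_homes": 5}, n_voters=9)
        with pytest.raises(ValidationError):
            apply_decision_rule(box, registry)

    def test_votes_bounded_by_voters(self):
        with pytest.raises(ValidationError):
            Ballotbox({"a": 10}, n_voters=9)


class TestResidualAfterRecommendation:
    def test_case_study_unspent_budget(self, registry, ballotbox):
        rec = apply_decision_rule(ballotbox, registry, threshold=6)
        assert residual_after_recommendation(rec, registry, 0.0) == pytest.approx(74.0)
        assert residual_after_recommendation(rec, registry, 60.0) == pytest.approx(134.0)

    def test_no_changes_leaves_the_release(self, registry):
        # current services all retained, new services all rejected
        votes = {
            c.id: (9 if c.currently_provided else 0)
            for c in registry
            if c.kind != "efficiency"
        }
        rec = apply_decision_rule(Ballotbox(votes, 9), registry, threshold=6)
        assert set(rec.decisions.values()) == {"Continue", "No investment"}
        assert residual_after_recommendation(rec, registry, 10.0) == pytest.approx(10.0)

    def test_symmetric_costs_cancel(self):
        registry = Registry(
            [_component("i1", "investment", 30.0), _component("d1", "disinvestment", 30.0)]
        )
        box = Ballotbox({"i1": 9, "d1": 0}, n_voters=9)
        rec = apply_decision_rule(box, registry, threshold=6)
        assert rec.decisions == {"i1": "Invest", "d1": "Disinvest"}
        assert residual_after_recommendation(rec, registry, 0.0) == 0.0
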