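"""Synthetic generators: seed discipline, constraint preservation, recovery."""

import numpy as np
import pandas as pd
import pytest

from pbma.errors import ConfigurationError
from pbma.synthetic import (
    SyntheticConfig,
    generate_panel_allocations,
    generate_regional_returns,
    generate_score_ballots,
    generate_subcriterion_allocations,
    generate_wtp_survey,
    true_final_scores,
)
from pbma.weights import aggregate_allocations


def _uniform_weights(n=11):
    return {f"crit_{i}": 1.0 / n for i in range(n)}


def _simple_config(**kwargs):
    defaults = dict(
        true_weights=_uniform_weights(),
        true_subweights={f"crit_{i}": {f"crit_{i}": 1.0} for i in range(11)},
        seed=123,
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            _simple_config(true_weights={"a": 0.5, "b": 0.6})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_panelists": 0},
            {"wtp_zero_prob": 1.5},
            {"score_noise_sd": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            _simple_config(**kwargs)


class TestPanelAllocations:
    def test_every_ballot_totals_exactly_100_nonnegative_integers(self):
        allocations = generate_panel_allocations(_simple_config())
        for a in allocations:
            values = np.array(list(a.points.values()))
            assert values.sum() == 100
            assert np.all(values >= 0)
            assert np.all(values == values.astype(int))

    def test_degenerate_weights_concentrate_all_points(self):
        weights = {"only": 1.0, "never": 0.0}
        config = _simple_config(
            true_weights=weights, true_subweights={k: {k: 1.0} for k in weights}
        )
        for a in generate_panel_allocations(config):
            assert a.points == {"only": 100.0, "never": 0.0}

    def test_same_seed_same_output(self):
        a = generate_panel_allocations(_simple_config())
        b = generate_panel_allocations(_simple_config())
        assert a == b

    def test_different_seed_different_output(self):
        a = generate_panel_allocations(_simple_config(seed=1))
        b = generate_panel_allocations(_simple_config(seed=2))
        assert a != b

    def test_large_panel_mean_recovers_uniform_weights(self):
        # law of large numbers: n=10 000 panelists over 11 equal criteria
        config = _simple_config(n_panelists=10_000)
        agg = aggregate_allocations(generate_panel_allocations(config))
        for weight in agg.values():
            assert abs(weight - 100.0 / 11) < 0.5

    def test_subcriterion_allocations_cover_each_criterion(self):
        config = SyntheticConfig(seed=5)
        per_criterion = generate_subcriterion_allocations(config)
        assert set(per_criterion) == set(config.true_weights)
        for allocs in per_criterion.values():
            assert all(a.total() == 100 for a in allocs)


class TestScoreBallots:
    def test_zero_noise_returns_exact_integer_truth(self):
        config = SyntheticConfig(score_noise_sd=0.0, seed=9)
        ballots = generate_score_ballots(config)
        truth = config.resolve_true_scores()
        for row in ballots.itertuples():
            assert row.score == truth.loc[row.component, (row.criterion, row.subcriterion)]

    def test_scores_always_inside_the_scale(self):
        config = SyntheticConfig(score_noise_sd=3.0, seed=10, n_panelists=3)
        scores = generate_score_ballots(config)["score"]
        assert scores.isin([-2, -1, 0, 1, 2]).all()

    def test_maximal_truth_never_exceeds_plus_two(self):
        config = SyntheticConfig(seed=11, n_components=2)
        truth = config.resolve_true_scores() * 0 + 2.0
        config = SyntheticConfig(
            seed=11, n_components=2, true_scores=truth, score_noise_sd=1.0
        )
        assert (generate_score_ballots(config)["score"] <= 2).all()

    def test_small_noise_median_recovers_truth(self):
        config = SyntheticConfig(seed=12, n_panelists=9, score_noise_sd=0.1)
        truth = config.resolve_true_scores() * 0 + 1.0
        config = SyntheticConfig(
            seed=12, n_panelists=9, score_noise_sd=0.1, true_scores=truth
        )
        ballots = generate_score_ballots(config)
        medians = ballots.groupby(["component", "subcriterion"])["score"].median()
        assert (medians == 1.0).all()


class TestWtpSurvey:
    def test_certain_zero_inflation(self):
        config = SyntheticConfig(wtp_zero_prob=1.0, seed=2, n_respondents=20)
        assert (generate_wtp_survey(config)["wtp_gbp_per_year"] == 0.0).all()

    def test_degenerate_lognormal_is_constant(self):
        config = SyntheticConfig(wtp_zero_prob=0.0, wtp_log_sd=0.0, wtp_log_mean=2.0, seed=3)
        values = generate_wtp_survey(config)["wtp_gbp_per_year"]
        assert np.allclose(values, np.exp(2.0))

    def test_zero_fraction_concentrates(self):
        config = SyntheticConfig(
            wtp_zero_prob=0.3, n_respondents=50_000, n_components=1, seed=4
        )
        values = generate_wtp_survey(config)["wtp_gbp_per_year"]
        assert abs((values == 0).mean() - 0.3) < 0.01

    def test_every_respondent_values_every_component(self):
        config = SyntheticConfig(n_respondents=25, n_components=4, seed=6)
        survey = generate_wtp_survey(config)
        counts = survey.groupby("respondent_id")["component"].nunique()
        assert (counts == 4).all()


class TestRegionalReturns:
    def test_full_response_returns_every_region(self):
        returns = generate_regional_returns(_simple_config(), n_regions=16, respond_fraction=1.0)
        assert len(returns) == 16

    def test_partial_response_returns_the_responding_subset(self):
        returns = generate_regional_returns(_simple_config(), n_regions=16, respond_fraction=9 / 16)
        assert len(returns) == 9

    def test_zero_noise_gives_identical_per_capita_spend(self):
        config = _simple_config(spend_noise_cv=0.0)
        returns = generate_regional_returns(config, n_regions=8, respond_fraction=1.0)
        line = next(iter(config.spend_per_capita_gbp))
        per_capita = {r.spend_by_line[line] / r.population for r in returns}
        assert len(per_capita) == 1

    def test_many_regions_recover_the_configured_mean(self):
        config = _simple_config(spend_per_capita_gbp={"line": 10.0}, spend_noise_cv=0.05)
        returns = generate_regional_returns(config, n_regions=400, respond_fraction=1.0)
        per_capita = np.array([r.spend_by_line["line"] / r.population for r in returns])
        assert abs(per_capita.mean() - 10.0) < 0.1  # within 1%

    def test_invalid_respond_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_regional_returns(_simple_config(), n_regions=4, respond_fraction=0.0)


class TestParameterRecovery:
    def test_true_final_scores_are_bounded_and_deterministic(self):
        config = SyntheticConfig(seed=0)
        finals = true_final_scores(config)
        assert finals.between(-2, 2).all()
        pd.testing.assert_series_equal(finals, true_final_scores(SyntheticConfig(seed=99)))
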