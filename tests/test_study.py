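"""Replication engine: tallies, precision arithmetic, naive power comparator."""

import numpy as np
import pytest

from eumodel import (
    ScenarioConfig,
    mc_precision,
    naive_logistic_power,
    run_classification_study,
    run_four_model_study,
    run_rejection_study,
)


class TestMcPrecision:
    def test_paper_scale_values(self):
        # the design precision of a 6000-replication study
        assert mc_precision(0.05, 6000) == pytest.approx(0.006, abs=5e-4)
        assert mc_precision(0.50, 6000) == pytest.approx(0.013, abs=5e-4)

    def test_vanishes_with_infinite_replications(self):
        assert mc_precision(0.5, 10**12) < 1e-5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mc_precision(0.0, 100)
        with pytest.raises(ValueError):
            mc_precision(0.5, 0)


class TestRejectionStudy:
    def test_alpha_zero_rejects_nothing(self):
        tab = run_rejection_study(
            [ScenarioConfig(n_cycles=150)],
            ("found_in_either", "global"),
            reps=8,
            alpha=0.0,
            base_seed=1,
        )
        assert (tab["proportion"] == 0.0).all()

    def test_table_structure_and_accounting(self):
        tab = run_rejection_study(
            [ScenarioConfig(n_cycles=150), ScenarioConfig(n_cycles=150, beta_ep2=0.5)],
            ("bonferroni",),
            reps=10,
            base_seed=2,
        )
        assert len(tab) == 2
        assert ((tab["n_valid"] + tab["n_dropped"]) == 10).all()
        assert tab["proportion"].between(0, 1).all()
        assert (tab.loc[tab["beta_ep2"] == 0.5, "metric"] == "rejection").all()

    def test_large_effect_large_sample_power_is_one(self):
        tab = run_rejection_study(
            [ScenarioConfig(n_cycles=3200, beta_ep2=1.0)],
            ("bonferroni", "global"),
            reps=15,
            base_seed=3,
        )
        assert (tab["proportion"] == 1.0).all()

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            run_rejection_study([ScenarioConfig(n_cycles=50)], ("magic",), reps=1)


class TestClassificationStudy:
    def test_strong_effect_classified_correctly(self):
        tab = run_classification_study(
            [ScenarioConfig(n_cycles=1600, beta_ep2=1.0)], reps=25, base_seed=4
        )
        row = tab[tab["metric"] == "correct_classification"].iloc[0]
        assert row["proportion"] >= 0.9

    def test_null_scenario_reports_selection_rate(self):
        tab = run_classification_study(
            [ScenarioConfig(n_cycles=200)], reps=30, base_seed=5
        )
        row = tab[tab["metric"] == "prop_select_E"].iloc[0]
        assert 0.0 <= row["proportion"] <= 1.0

    def test_bin_rows_pool_only_single_effect_scenarios(self):
        tab = run_classification_study(
            [
                ScenarioConfig(n_cycles=200),  # null: excluded from bins
                ScenarioConfig(n_cycles=200, beta_up=0.6),
            ],
            reps=20,
            base_seed=6,
        )
        bins = tab[tab["metric"] == "bin_correct"]
        assert bins["n_valid"].sum() == 20
        assert set(bins["strategy_or_criterion"]).issubset(
            {"[0,2)", "[2,6)", "[6,10)", ">=10"}
        )

    def test_effect_in_both_submodels_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            run_classification_study(
                [ScenarioConfig(n_cycles=100, beta_up=0.5, beta_ep2=0.5)], reps=1
            )


class TestFourModelStudy:
    def test_proportions_partition_unity(self):
        tab = run_four_model_study(
            [ScenarioConfig(n_cycles=300, beta_ep2=0.5)], reps=12, criterion="bic",
            base_seed=7,
        )
        assert tab["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        labels = set(tab["strategy_or_criterion"])
        assert labels == {"bic:null", "bic:E", "bic:U", "bic:EU", "bic:tie"}

    def test_null_scenario_prefers_null_under_bic(self):
        tab = run_four_model_study(
            [ScenarioConfig(n_cycles=1600)], reps=20, criterion="bic", base_seed=8
        )
        null_prop = tab.loc[
            tab["strategy_or_criterion"] == "bic:null", "proportion"
        ].iloc[0]
        assert null_prop >= 0.8


class TestPowerOrderings:
    """Pre-specification gains/losses and the naive comparator's optimism."""

    def test_prespecification_and_naive_power_orderings(self):
        # true effect on the embryo side: testing in the correct sub-model
        # beats Bonferroni, testing in the wrong one loses more than the
        # correct one gains; the fully observed single-level logistic power
        # overstates all of them
        scenario = ScenarioConfig(n_cycles=800, beta_ep2=0.3)
        tab = run_rejection_study(
            [scenario],
            ("bonferroni", "prespecified_E", "prespecified_U"),
            reps=500,
            base_seed=78,
        )
        power = dict(zip(tab["strategy_or_criterion"], tab["proportion"]))
        assert power["prespecified_E"] > power["bonferroni"] > power["prespecified_U"]
        naive = naive_logistic_power(0.3, n=800, event_rate=0.197, reps=400, base_seed=78)
        assert naive > power["bonferroni"]


class TestNaiveLogisticPower:
    def test_null_effect_matches_alpha(self):
        power = naive_logistic_power(0.0, n=400, event_rate=0.197, reps=600, base_seed=9)
        assert power == pytest.approx(0.05, abs=3 * mc_precision(0.05, 600) / 1.96)

    def test_power_increases_with_sample_size(self):
        p_small = naive_logistic_power(0.3, n=100, event_rate=0.197, reps=300, base_seed=10)
        p_large = naive_logistic_power(0.3, n=1000, event_rate=0.197, reps=300, base_seed=10)
        assert p_large > p_small

    def test_invalid_event_rate_rejected(self):
        with pytest.raises(ValueError):
            naive_logistic_power(0.1, 100, 1.5, reps=1)
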