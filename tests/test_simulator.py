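"""Trial simulator and (stratified) log-rank test."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from smalltrial import (
    AccrualPlan,
    DesignError,
    ErrorSpec,
    SimulationConfig,
    StratumSpec,
    SurvivalAssumption,
    build_design,
    estimate_operating_characteristics,
    generate_trial,
    logrank_test,
)


def brute_force_logrank(time, event, arm):
    """Independent risk-set enumeration of O1 - E1 and its variance."""
    o_minus_e = variance = 0.0
    for t in sorted({t for t, e in zip(time, event) if e}):
        at_risk = [i for i, ti in enumerate(time) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if arm[i] == 1)
        deaths = [i for i, (ti, ei) in enumerate(zip(time, event)) if ei and ti == t]
        d = len(deaths)
        d1 = sum(1 for i in deaths if arm[i] == 1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, variance


def as_frame(time, event, arm, stratum=None):
    return pd.DataFrame(
        {
            "id": range(len(time)),
            "arm": arm,
            "stratum": stratum if stratum is not None else [0] * len(time),
            "entry_time": [0.0] * len(time),
            "observed_time": time,
            "event_indicator": event,
        }
    )


def small_design(formula="schoenfeld"):
    return build_design(
        ErrorSpec(0.05, "two", 0.80),
        SurvivalAssumption(0.70, 3.0, 0.63),
        AccrualPlan(3.5, 5.0),
        formula=formula,
    )


class TestLogrank:
    def test_toy_dataset_matches_brute_force_oracle(self):
        # arm 0 events at t = 1, 2; arm 1 events at t = 1.5, 3; no censoring
        time = [1.0, 2.0, 1.5, 3.0]
        event = [1, 1, 1, 1]
        arm = [0, 0, 1, 1]
        oe, v = brute_force_logrank(time, event, arm)
        result = logrank_test(as_frame(time, event, arm))
        assert result.statistic == pytest.approx(oe / math.sqrt(v), rel=1e-12)
        assert result.p_value == pytest.approx(
            2 * (1 - 0.5 * (1 + math.erf(abs(oe / math.sqrt(v)) / math.sqrt(2)))), rel=1e-9
        )

    def test_random_dataset_matches_oracle_with_ties_and_censoring(self):
        rng = np.random.default_rng(11)
        time = rng.integers(1, 8, size=40).astype(float)  # heavy ties
        event = rng.integers(0, 2, size=40)
        arm = rng.permutation(np.repeat([0, 1], 20))
        if event.sum() == 0:  # pragma: no cover - seed chosen to avoid this
            event[0] = 1
        oe, v = brute_force_logrank(time.tolist(), event.tolist(), arm.tolist())
        result = logrank_test(as_frame(time, event, arm))
        assert result.statistic == pytest.approx(oe / math.sqrt(v), rel=1e-10)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        n = 120
        arm = rng.permutation(np.repeat([0, 1], n // 2))
        time = rng.exponential(1.0, n) * np.where(arm == 1, 1.6, 1.0)
        event = (time < 2.0).astype(int)
        time = np.minimum(time, 2.0)
        ours = logrank_test(as_frame(time, event, arm))
        theirs = lifelines_logrank(
            time[arm == 0], time[arm == 1], event[arm == 0], event[arm == 1]
        )
        assert ours.statistic**2 == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_identical_arms_give_null_statistic(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1] * 6
        arm = [0, 0, 0, 1, 1, 1]
        result = logrank_test(as_frame(time, event, arm))
        assert result.statistic == 0.0
        assert result.p_value == 1.0
        assert result.direction == "none"

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(1.0, 30)
        event = np.ones(30, dtype=int)
        arm = rng.permutation(np.repeat([0, 1], 15))
        frame = as_frame(time, event, arm)
        assert logrank_test(frame, strata=True).statistic == pytest.approx(
            logrank_test(frame, strata=False).statistic, rel=1e-12
        )

    def test_zero_events_undefined(self):
        with pytest.raises(DesignError):
            logrank_test(as_frame([1.0, 2.0], [0, 0], [0, 1]))

    def test_one_sided_p_reports_benefit_direction(self):
        # experimental arm (1) events much later -> benefit, small one-sided p
        time = [0.5, 0.7, 0.9, 5.0, 6.0, 7.0]
        event = [1] * 6
        arm = [0, 0, 0, 1, 1, 1]
        result = logrank_test(as_frame(time, event, arm), sidedness="one")
        assert result.direction == "benefit"
        assert result.p_value < 0.05
        harm = logrank_test(as_frame(time, event, [1, 1, 1, 0, 0, 0]), sidedness="one")
        assert harm.direction == "harm"
        assert harm.p_value > 0.5


class TestGenerateTrial:
    def test_seeded_replay_is_identical(self):
        config = SimulationConfig(small_design(), 0.63, replications=1, seed=42)
        a = generate_trial(config, np.random.default_rng(123))
        b = generate_trial(config, np.random.default_rng(123))
        pd.testing.assert_frame_equal(a, b)
        assert a.attrs["analysis_time"] == b.attrs["analysis_time"]

    def test_columns_and_allocation(self):
        config = SimulationConfig(small_design(), 0.63, replications=1, seed=0)
        df = generate_trial(config, np.random.default_rng(0))
        assert list(df.columns) == [
            "id", "arm", "stratum", "entry_time", "observed_time", "event_indicator",
        ]
        assert df["arm"].sum() == len(df) // 2  # 1:1 permuted allocation
        assert (df["entry_time"] <= 3.5).all()

    def test_event_driven_analysis_stops_at_required_events(self):
        config = SimulationConfig(small_design(), 0.63, replications=1, seed=9)
        df = generate_trial(config, np.random.default_rng(9))
        assert df["event_indicator"].sum() == 147

    def test_null_hazard_balance_between_arms(self):
        """Under HR 1, arm event counts differ by only binomial noise."""
        config = SimulationConfig(small_design(), 1.0, replications=1, seed=1, patients=2000)
        df = generate_trial(config, np.random.default_rng(1))
        events = df.loc[df["event_indicator"] == 1, "arm"]
        se = 0.5 * math.sqrt(len(events))
        assert abs(events.sum() - len(events) / 2) < 4 * se

    def test_zero_hazard_yields_no_events(self):
        design = build_design(
            ErrorSpec(0.05, "two", 0.80),
            SurvivalAssumption(0.9999999999, 3.0, 0.63),
            AccrualPlan(3.5, 5.0),
        )
        config = SimulationConfig(design, 0.63, replications=1, seed=2, patients=50)
        df = generate_trial(config, np.random.default_rng(2))
        assert df["event_indicator"].sum() == 0

    def test_stratum_membership_probabilities(self):
        spec = StratumSpec((1.0, 2.0), (0.5, 0.5))
        config = SimulationConfig(
            small_design(), 0.63, replications=1, seed=3, stratum_spec=spec, patients=4000
        )
        df = generate_trial(config, np.random.default_rng(3))
        share = (df["stratum"] == 1).mean()
        assert abs(share - 0.5) < 4 * 0.5 / math.sqrt(4000)


class TestOperatingCharacteristics:
    def test_null_rejection_near_alpha(self):
        config = SimulationConfig(small_design(), 1.0, replications=2000, seed=17)
        result = estimate_operating_characteristics(config)
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(result.rejection_rate - 0.05) < 3 * se

    def test_one_sided_null_rejection_near_alpha(self):
        design = build_design(
            ErrorSpec(0.05, "one", 0.80),
            SurvivalAssumption(0.70, 3.0, 0.63),
            AccrualPlan(3.5, 5.0),
            formula="schoenfeld",
        )
        config = SimulationConfig(design, 1.0, replications=2000, seed=18)
        result = estimate_operating_characteristics(config)
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(result.rejection_rate - 0.05) < 3 * se

    def test_power_near_nominal(self):
        config = SimulationConfig(small_design(), 0.63, replications=2000, seed=19)
        result = estimate_operating_characteristics(config)
        assert abs(result.rejection_rate - 0.80) < 0.80 * 0.05 + 3 * result.mc_standard_error
        assert result.mean_events_at_analysis == pytest.approx(147.0)

    def test_single_replication_degenerate(self):
        config = SimulationConfig(small_design(), 0.63, replications=1, seed=4)
        result = estimate_operating_characteristics(config)
        assert result.rejection_rate in (0.0, 1.0)
        assert result.mc_standard_error == 0.0

    def test_results_are_seed_reproducible(self):
        config = SimulationConfig(small_design(), 0.63, replications=200, seed=5)
        assert estimate_operating_characteristics(config) == estimate_operating_characteristics(
            config
        )

    def test_stratified_analysis_recovers_power(self):
        """A prognostic stratum analysed within strata never loses power."""
        spec = StratumSpec((0.6, 2.0), (0.5, 0.5))
        base = dict(
            design=small_design(), true_hazard_ratio=0.7, replications=800, seed=23,
            stratum_spec=spec,
        )
        unstratified = estimate_operating_characteristics(
            SimulationConfig(**base, stratified_analysis=False)
        )
        stratified = estimate_operating_characteristics(
            SimulationConfig(**base, stratified_analysis=True)
        )
        assert stratified.rejection_rate >= unstratified.rejection_rate

    def test_invalid_configs_rejected(self):
        with pytest.raises(DesignError):
            SimulationConfig(small_design(), 0.63, replications=0, seed=1)
        with pytest.raises(DesignError):
            SimulationConfig(small_design(), 0.63, replications=10, seed=1,
                             stratified_analysis=True)
        with pytest.raises(DesignError):
            StratumSpec((1.0, 2.0), (0.6, 0.6))
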