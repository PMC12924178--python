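"""Cumulative delivery time and breathing-phase interplay mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protonbdt as p
from protonbdt.applications import (BreathingTrace, PhaseMap, breathing_phase,
                                    compare_phase_maps, compare_timing_sources,
                                    cumulative_bdt, interplay_experiment,
                                    map_pulses_to_phases, predict_plan_timing)


class TestCumulative:
    def test_single_transition(self):
        assert list(cumulative_bdt([100.0])) == [100.0]

    def test_running_sum(self):
        assert list(cumulative_bdt([1.0, 2.0, 3.0])) == [1.0, 3.0, 6.0]

    def test_total_is_permutation_invariant(self):
        dts = np.array([5.0, 80.0, 1200.0, 7.0])
        assert cumulative_bdt(dts)[-1] == cumulative_bdt(dts[::-1])[-1]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cumulative_bdt([1.0, 0.0])


class TestTimingComparison:
    def test_identical_sources(self):
        c = compare_timing_sources([10.0, 20.0], [10.0, 20.0])
        assert c.relative_deviation == 0.0

    def test_uniform_one_percent_inflation(self):
        ref = np.array([10.0, 500.0, 1500.0])
        c = compare_timing_sources(ref, 1.01 * ref)
        assert c.relative_deviation == pytest.approx(0.01)

    def test_sign_convention_predicted_minus_actual(self):
        c = compare_timing_sources([100.0], [90.0])
        assert c.relative_deviation < 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_timing_sources([1.0, 2.0], [1.0])


class TestBreathingPhase:
    def test_zero_time_zero_offset(self):
        trace = BreathingTrace(period=4.0)
        assert breathing_phase(0.0, trace) == 0

    def test_periodicity(self):
        trace = BreathingTrace(period=4.0, n_phases=10)
        for t in [0.0, 0.7, 2.2, 3.9]:
            assert breathing_phase(t, trace) == breathing_phase(t + 4.0, trace)

    def test_half_period_with_four_phases(self):
        trace = BreathingTrace(period=4.0, n_phases=4)
        assert breathing_phase(2.0, trace) == 2

    def test_amplitude_is_metadata_only(self):
        a = BreathingTrace(period=3.0, amplitude=1.0)
        b = BreathingTrace(period=3.0, amplitude=25.0)
        t = np.linspace(0, 30, 200)
        assert np.array_equal(breathing_phase(t, a), breathing_phase(t, b))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 1e4, allow_nan=False),
           st.floats(0.5, 10.0, allow_nan=False),
           st.integers(1, 20))
    def test_phase_in_range(self, t, period, n_phases):
        trace = BreathingTrace(period=period, n_phases=n_phases)
        assert 0 <= breathing_phase(t, trace) < n_phases


class TestPhaseMapping:
    def test_early_pulses_all_in_phase_zero(self):
        trace = BreathingTrace(period=4.0, n_phases=10)  # phase 0 spans 0-400 ms
        pm = map_pulses_to_phases([0.0, 100.0, 300.0], [5.0, 8.0, 8.0], trace)
        assert pm.charge_pc[0] == pytest.approx(21.0)
        assert pm.charge_pc[1:].sum() == 0.0

    def test_charge_conservation_exact(self, tiny_logs):
        frac = tiny_logs[(tiny_logs["fraction_id"] == "f01")
                         & (tiny_logs["beam_id"] == "b01")]
        trace = BreathingTrace(period=4.0)
        pm = map_pulses_to_phases(frac["timestamp_ms"].to_numpy(),
                                  frac["target_charge_pC"].to_numpy(), trace)
        assert pm.charge_pc.sum() == pytest.approx(
            frac["target_charge_pC"].sum(), rel=1e-12)

    def test_equidistribution_of_incommensurate_constant_interval(self):
        trace = BreathingTrace(period=2.0, n_phases=10)
        ts = np.arange(20_000) * 37.0  # 37 ms never locks onto a 2 s cycle
        pm = map_pulses_to_phases(ts, np.ones(20_000), trace)
        shares = pm.distribution
        assert np.all(np.abs(shares - 0.1) <= 0.02)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            map_pulses_to_phases([0.0, 10.0, 5.0], [1.0, 1.0, 1.0],
                                 BreathingTrace(period=2.0))


class TestPhaseMapComparison:
    def _pm(self, charges, labels):
        return PhaseMap(np.asarray(charges, dtype=float),
                        np.asarray(labels), 2.0, len(charges))

    def test_identical_maps(self):
        a = self._pm([3.0, 1.0], [0, 0, 1])
        assert compare_phase_maps(a, a) == {"agreement": 1.0, "tv_distance": 0.0}

    def test_disjoint_single_phase_maps(self):
        a = self._pm([4.0, 0.0], [0, 0])
        b = self._pm([0.0, 4.0], [1, 1])
        out = compare_phase_maps(a, b)
        assert out["agreement"] == 0.0
        assert out["tv_distance"] == 1.0

    def test_hand_computed_tv(self):
        a = self._pm([3.0, 1.0], [0, 1])
        b = self._pm([1.0, 3.0], [0, 1])
        assert compare_phase_maps(a, b)["tv_distance"] == pytest.approx(0.5)

    def test_mismatched_structure_rejected(self):
        a = self._pm([1.0, 1.0], [0, 1])
        b = self._pm([1.0, 1.0, 1.0], [0, 1])
        with pytest.raises(ValueError):
            compare_phase_maps(a, b)


class _OracleResults:
    """Stand-in results object predicting with a fixed delta-t oracle."""

    def __init__(self, dt_by_beam, training_ids=frozenset()):
        self.dt_by_beam = dt_by_beam
        self.training_ids = training_ids
        self._cursor = {}

    def predict(self, feats):
        # features arrive beam by beam in delivery order
        for beam, dt in self.dt_by_beam.items():
            if len(dt) == len(feats) and beam not in self._cursor:
                self._cursor[beam] = True
                return dt
        raise AssertionError("unexpected feature block")


class TestInterplayExperiment:
    def test_oracle_timings_zero_noise_give_zero_tv(self, quiet_config):
        plan = p.generate_plan(31, 1, 3, 9, quiet_config, beam_prefix="z")
        logs = p.simulate_course(plan, 3, 32, quiet_config)
        f1 = logs[logs["fraction_id"] == "f01"]
        dt_by_beam = {b: np.diff(g.sort_values("pulse_index")["timestamp_ms"].to_numpy())
                      for b, g in f1.groupby("beam_id")}
        oracle = _OracleResults(dt_by_beam)
        summary = interplay_experiment(plan, oracle, logs, config=quiet_config)
        assert len(summary) == 3
        assert np.allclose(summary["model_tv_mean"], 0.0, atol=1e-12)
        assert (summary["intrinsic_tv_max"] == 0.0).all()

    def test_three_periods_reported(self, quiet_config):
        plan = p.generate_plan(33, 1, 2, 9, quiet_config, beam_prefix="q")
        logs = p.simulate_course(plan, 2, 34, quiet_config)
        f1 = logs[logs["fraction_id"] == "f01"]
        dt_by_beam = {b: np.diff(g.sort_values("pulse_index")["timestamp_ms"].to_numpy())
                      for b, g in f1.groupby("beam_id")}
        summary = interplay_experiment(plan, _OracleResults(dt_by_beam), logs,
                                       periods_s=(2.0, 4.0, 5.0),
                                       config=quiet_config)
        assert summary["period_s"].tolist() == [2.0, 4.0, 5.0]

    def test_leakage_is_rejected(self, quiet_config):
        plan = p.generate_plan(35, 1, 2, 9, quiet_config, beam_prefix="t")
        logs = p.simulate_course(plan, 2, 36, quiet_config)
        beam = plan["beam_id"].iloc[0]
        oracle = _OracleResults({}, training_ids=frozenset({("f01", beam)}))
        with pytest.raises(ValueError, match="training set"):
            interplay_experiment(plan, oracle, logs, config=quiet_config)


class TestPlanTimingPrediction:
    def test_timestamps_start_at_zero_and_increase(self, small_fit, tiny_plan, config):
        _, _, res = small_fit
        predicted = predict_plan_timing(res, tiny_plan, config)
        for _, g in predicted.groupby("beam_id"):
            ts = g["timestamp_ms"].to_numpy()
            assert ts[0] == 0.0
            assert (np.diff(ts) > 0).all()

    def test_pulse_count_matches_plan_expansion(self, small_fit, tiny_plan, config):
        _, _, res = small_fit
        predicted = predict_plan_timing(res, tiny_plan, config)
        assert len(predicted) == len(p.plan_to_pulses(tiny_plan, config))
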