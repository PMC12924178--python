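"""Delivery-physics simulator: energy table, plates, plan and log generation."""

import numpy as np
import pandas as pd
import pytest

import protonbdt as p
from protonbdt.machine import _transition_kinematics, _deterministic_dt_from_kin
from protonbdt.schema import leaf_columns


def _pulse(x=0.0, y=0.0, level=10, charge=5.0, low=False, leaf_shift=(0.0, 0.0),
           shifted_leaves=0, config=None):
    """A pulse record dict; optionally shift the first k leaves by a vector."""
    config = config or p.MachineConfig()
    rec = {"x_mm": x, "y_mm": y, "energy_level": level,
           "target_charge_pC": charge, "is_low_charge": low}
    leaves = np.zeros((config.n_leaves, 2))
    leaves[np.arange(config.n_leaves) % 2 == 0, 0] = 5.0  # arbitrary resting shape
    leaves[:shifted_leaves] += np.asarray(leaf_shift)
    for col, val in zip(leaf_columns(config.n_leaves), leaves.ravel()):
        rec[col] = val
    return rec


class TestEnergyTable:
    def test_count_spacing_and_endpoints(self, config):
        table = p.energy_table(config)
        assert len(table) == 161
        assert table[0] == 0.0
        assert table[-1] == pytest.approx(336.0)
        assert np.allclose(np.diff(table), 2.1)


class TestPlates:
    def test_level_zero_all_retracted(self, config):
        assert not p.plate_configuration(0, config).any()

    def test_binary_decomposition(self, config):
        occ = p.plate_configuration(5, config)
        assert list(np.nonzero(occ)[0]) == [0, 2]  # weights 1 and 4

    def test_bijection_over_all_levels(self, config):
        occs = {tuple(p.plate_configuration(k, config))
                for k in range(config.n_energy_levels)}
        assert len(occs) == config.n_energy_levels

    def test_occupancy_realises_level(self, config):
        weights = 2 ** np.arange(8)
        for k in [0, 1, 7, 64, 160]:
            occ = p.plate_configuration(k, config)
            assert int((occ[:8] * weights).sum()) == k

    @pytest.mark.parametrize("a, b, expected", [(9, 9, 0), (0, 1, 1), (3, 4, 3)])
    def test_plates_moved(self, config, a, b, expected):
        assert p.plates_moved(a, b, config) == expected
        assert p.plates_moved(b, a, config) == expected

    def test_out_of_range_level(self, config):
        with pytest.raises(ValueError):
            p.plate_configuration(161, config)
        with pytest.raises(ValueError):
            p.plates_moved(-1, 0, config)


class TestSpotSplitting:
    @pytest.mark.parametrize("charge, expected", [
        (5.0, [5.0]), (8.0, [8.0]), (20.0, [8.0, 8.0, 4.0])])
    def test_fill_to_cap(self, config, charge, expected):
        assert list(p.split_spot_to_pulses(charge, config)) == expected

    def test_charge_conserved_and_capped(self, config):
        for charge in [0.3, 7.9, 8.1, 16.0, 29.5]:
            pulses = p.split_spot_to_pulses(charge, config)
            assert pulses.sum() == pytest.approx(charge)
            assert (pulses <= config.max_pulse_charge).all()

    def test_nonpositive_charge_rejected(self, config):
        with pytest.raises(ValueError):
            p.split_spot_to_pulses(0.0, config)


class TestPlanGeneration:
    def test_prelude_layer_prepended(self, config):
        plan = p.generate_plan(0, 1, 1, 1, config)
        assert sorted(plan["layer_index"].unique()) == [0, 1]
        prelude = plan[plan["layer_index"] == 0]
        assert prelude["is_low_charge"].all()
        assert (prelude["charge_pC"] == config.low_charge).all()

    def test_spots_within_field(self, config):
        plan = p.generate_plan(3, 3, 6, 49, config)
        assert plan[["x_mm", "y_mm"]].abs().to_numpy().max() <= 100.0

    def test_seeded_determinism(self, config):
        a = p.generate_plan(5, 2, 3, 9, config)
        b = p.generate_plan(5, 2, 3, 9, config)
        pd.testing.assert_frame_equal(a, b)

    def test_treatment_layers_descend_in_energy(self, config):
        plan = p.generate_plan(4, 1, 6, 4, config)
        tx = plan[~plan["is_low_charge"]]
        levels = tx.groupby("layer_index")["energy_level"].first()
        assert (np.diff(levels.to_numpy()) < 0).all()


class TestDeterministicDeltaT:
    def test_no_change_transition(self, config):
        a = _pulse()
        assert p.deterministic_delta_t(a, dict(a), config) == pytest.approx(7.0)

    def test_aperture_only_transition(self, config):
        a = _pulse()
        b = _pulse(shifted_leaves=1, leaf_shift=(100.0, 0.0))
        assert p.deterministic_delta_t(a, b, config) == pytest.approx(257.0)

    def test_energy_change_transition(self, config):
        a = _pulse(level=3)
        b = _pulse(level=4)  # 3 plates moved under the binary scheme
        assert p.deterministic_delta_t(a, b, config) == pytest.approx(1267.0)

    def test_regime_bands(self, config):
        a = _pulse()
        assert p.deterministic_delta_t(a, dict(a), config) < 50.0
        for daa in [1.0, 100.0, 450.0]:
            b = _pulse(shifted_leaves=1, leaf_shift=(daa, 0.0))
            assert 50.0 <= p.deterministic_delta_t(a, b, config) <= 1000.0
        for lb in [1, 64, 160]:
            b = _pulse(level=lb)
            if lb != a["energy_level"]:
                assert p.deterministic_delta_t(a, b, config) > 1000.0

    def test_monotone_in_aperture_travel(self, config):
        a = _pulse()
        dts = [p.deterministic_delta_t(a, _pulse(shifted_leaves=1, leaf_shift=(s, 0.0)), config)
               for s in [0.0, 10.0, 50.0, 200.0, 400.0]]
        assert (np.diff(dts) >= 0).all()

    def test_flag_surcharges(self, config):
        a = _pulse(low=True, charge=5.0)
        b = _pulse(low=False, charge=5.0)
        base = p.deterministic_delta_t(a, dict(a), config)
        assert p.deterministic_delta_t(a, b, config) == pytest.approx(base + 400.0)
        assert (p.deterministic_delta_t(a, dict(a), config, is_first=True)
                == pytest.approx(base + 200.0))


class TestSimulation:
    def test_zero_noise_matches_deterministic_sum(self, tiny_plan, quiet_config):
        log = p.simulate_fraction(tiny_plan, 1, quiet_config)
        for _, beam in log.groupby("beam_id"):
            kin = _transition_kinematics(beam.reset_index(drop=True), quiet_config)
            dt = _deterministic_dt_from_kin(kin, quiet_config)
            expected = np.concatenate([[0.0], np.cumsum(dt)])
            assert np.allclose(beam["timestamp_ms"].to_numpy(), expected, atol=1e-3)

    def test_seeded_reproducibility(self, tiny_plan, config):
        a = p.simulate_fraction(tiny_plan, 42, config)
        b = p.simulate_fraction(tiny_plan, 42, config)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_affects_timing_only(self, tiny_plan, config):
        a = p.simulate_fraction(tiny_plan, 1, config)
        b = p.simulate_fraction(tiny_plan, 2, config)
        cols = [c for c in a.columns if c != "timestamp_ms"]
        pd.testing.assert_frame_equal(a[cols], b[cols])
        assert not np.allclose(a["timestamp_ms"], b["timestamp_ms"])

    def test_regime_coverage(self, config):
        plan = p.generate_plan(2, 1, 5, 25, config)
        log = p.simulate_fraction(plan, 3, config)
        dt = np.diff(log["timestamp_ms"].to_numpy())
        assert (dt < 50).mean() > 0
        assert (dt > 1000).mean() > 0

    def test_timestamps_strictly_increasing(self, tiny_logs):
        for _, beam in tiny_logs.groupby(["fraction_id", "beam_id"]):
            assert (np.diff(beam["timestamp_ms"].to_numpy()) > 0).all()

    def test_charges_capped_and_low_layer_fixed(self, tiny_logs, config):
        assert (tiny_logs["target_charge_pC"] <= config.max_pulse_charge).all()
        low = tiny_logs[tiny_logs["is_low_charge"]]
        assert (low["target_charge_pC"] == config.low_charge).all()

    def test_course_shares_pulse_sequence(self, tiny_plan, config):
        logs = p.simulate_course(tiny_plan, 3, 0, config)
        ref = None
        for _, frac in logs.groupby("fraction_id"):
            key = frac[["beam_id", "pulse_index", "x_mm", "y_mm",
                        "energy_level"]].reset_index(drop=True)
            if ref is None:
                ref = key
            else:
                pd.testing.assert_frame_equal(ref, key)

    def test_single_fraction_course(self, tiny_plan, config):
        logs = p.simulate_course(tiny_plan, 1, 0, config)
        assert logs["fraction_id"].nunique() == 1

    def test_interfraction_noise_is_zero_mean(self, config, quiet_config):
        plan = p.generate_plan(11, 1, 2, 9, config)
        no_outliers = p.MachineConfig(noise=p.NoiseParams(outlier_prob=0.0))
        logs = p.simulate_course(plan, 30, 12, no_outliers)
        var = p.interfraction_variability(logs)
        res = var["residuals"]["residual_ms"]
        # residuals share the reference fraction's noise, so bound the mean
        # with the (correlated) sampling variance of the noise model itself
        det = p.simulate_fraction(plan, 0, quiet_config)
        dt_det = np.diff(det["timestamp_ms"].to_numpy())
        sigma = no_outliers.noise.sigma_floor + no_outliers.noise.sigma_rel * dt_det
        n, k = len(dt_det), 29
        bound = 4.0 * np.sqrt((1.0 + 1.0 / k) * np.sum(sigma**2)) / n
        assert abs(res.mean()) < bound

    def test_repainted_plan_structure(self, config):
        plan = p.generate_plan(13, 1, 3, 4, config)
        rep = p.make_repainted_plan(plan, 3, config)
        tx = plan[~plan["is_low_charge"]]
        assert len(rep) == len(plan) + 2 * len(tx)
        levels = rep[~rep["is_low_charge"]].groupby("layer_index", sort=True)[
            "energy_level"].first().to_numpy()
        # each pass repeats the same descending sequence
        assert list(levels) == list(levels[:3]) * 3
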