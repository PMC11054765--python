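"""Generator ground truth: determinism, analytic oracles, stream structure."""
import numpy as np
import pytest

from cpts.errors import ConfigurationError, InfeasibilityError
from cpts.activity import detect_strides
from cpts.synth import (GenerationConfig, generate_cohort, generate_profile,
                        halfsine_pti, simulate_acceleration,
                        simulate_pressure_trial, simulate_stride_stream,
                        simulate_temperature_log, simulate_thermal_pair)
from cpts.thermal import thermal_stress_response
from cpts.types import Condition, WearIntervalSet

from conftest import fixed_profile


class TestGenerateProfile:
    def test_ranges_and_determinism(self):
        cfg = GenerationConfig.au_study()
        p = generate_profile(1, cfg)
        assert 0.0 <= p.true_adherence <= 1.0
        assert cfg.daily_strides_range[0] <= p.true_daily_strides \
            <= cfg.daily_strides_range[1]
        assert p.__dict__ == generate_profile(1, cfg).__dict__

    def test_degenerate_range_pins_value(self):
        cfg = GenerationConfig.au_study(adherence_range=(0.509, 0.509))
        assert generate_profile(1, cfg).true_adherence == pytest.approx(0.509)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            GenerationConfig(adherence_range=(0.7, 0.2))

    def test_nl_style_has_no_thermal_targets(self):
        p = generate_profile(3, GenerationConfig.nl_study())
        assert p.tsr_in_device is None and p.tsr_non_device is None


class TestTemperatureLog:
    def test_always_worn_approaches_skin_setpoint(self):
        p = fixed_profile(wear_schedule=[(0.0, 24.0)])
        log = simulate_temperature_log(p, 1, noise_sd=0.0)
        assert log.temps_c[-1] == pytest.approx(32.0, abs=1e-6)
        assert np.all(np.diff(log.temps_c) >= -1e-12)  # monotone warm-up

    def test_never_worn_stays_ambient(self):
        p = fixed_profile(true_adherence=0.0, wear_schedule=[(8.0, 8.25)])
        p.wear_schedule = []  # bypass: schedule-free profile, off throughout
        log = simulate_temperature_log(p, 1, noise_sd=0.0, initial_c=21.0)
        assert np.allclose(log.temps_c, 21.0)

    def test_first_order_closed_form(self):
        """Noise-free samples match T(t) = set + (T0 - set) exp(-t/tau)."""
        p = fixed_profile(wear_schedule=[(8.0, 20.0)], monitoring_days=6)
        log = simulate_temperature_log(p, 1, noise_sd=0.0)
        # samples 08:00..20:00 of day one: indices 32..80
        tau = 30.0
        t_min = 15.0 * np.arange(0, 49)
        expected_rise = 32.0 + (21.0 - 32.0) * np.exp(-t_min / tau)
        np.testing.assert_allclose(log.temps_c[32:81], expected_rise, atol=1e-9)
        expected_fall = 21.0 + (expected_rise[-1] - 21.0) * np.exp(-t_min[1:17] / tau)
        np.testing.assert_allclose(log.temps_c[81:97], expected_fall, atol=1e-9)

    def test_sampling_grid(self):
        p = fixed_profile(monitoring_days=6)
        log = simulate_temperature_log(p, 1)
        assert len(log.temps_c) == 6 * 96
        assert np.all(log.spacings_min() == 15.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_temperature_log(fixed_profile(), 1, noise_sd=-0.1)


class TestStrideStream:
    @pytest.mark.parametrize("adherence,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_extreme_adherence(self, adherence, expect):
        p = fixed_profile(true_adherence=adherence)
        s = simulate_stride_stream(p, 1)
        wear = WearIntervalSet(p.wear_intervals_abs())
        assert wear.contains(s.timestamps).mean() == expect

    def test_adherence_fraction_to_rounding_granularity(self):
        p = fixed_profile(true_adherence=0.481)
        s = simulate_stride_stream(p, 2)
        wear = WearIntervalSet(p.wear_intervals_abs())
        frac = wear.contains(s.timestamps).mean()
        assert abs(frac - 0.481) <= 1.0 / p.true_daily_strides

    def test_mean_daily_count_near_target(self):
        p = fixed_profile(true_daily_strides=2146, monitoring_days=6)
        s = simulate_stride_stream(p, 3)
        per_day = s.per_day_counts()
        assert len(per_day) == 6
        assert abs(per_day.mean() - 2146) / 2146 < 0.05

    def test_no_nocturnal_strides(self):
        s = simulate_stride_stream(fixed_profile(), 4)
        hours = (s.timestamps - s.timestamps.astype("datetime64[D]")
                 ).astype("timedelta64[h]").astype(int)
        assert hours.min() >= 6

    def test_empty_schedule_with_positive_adherence_infeasible(self):
        p = fixed_profile()
        p.wear_schedule = []
        with pytest.raises(InfeasibilityError):
            simulate_stride_stream(p, 1)

    def test_inter_stride_spacing(self):
        s = simulate_stride_stream(fixed_profile(), 5)
        gaps = np.diff(s.timestamps).astype("timedelta64[ms]").astype(float)
        assert gaps.min() >= 400.0


class TestAcceleration:
    def test_zero_strides_zero_peaks(self):
        from cpts.types import StrideEventSeries
        empty = StrideEventSeries(np.array([], dtype="datetime64[ns]"))
        t0 = np.datetime64("2024-03-04T10:00:00", "ns")
        acc = simulate_acceleration(empty, 100.0, 1,
                                    window=(t0, t0 + np.timedelta64(60, "s")))
        assert len(detect_strides(acc)) == 0

    def test_clean_signal_one_peak_per_stride(self):
        from cpts.types import StrideEventSeries
        t0 = np.datetime64("2024-03-04T10:00:00", "ns")
        ts = t0 + (np.arange(100) * 1.1e9).astype("timedelta64[ns]")
        acc = simulate_acceleration(StrideEventSeries(ts), 100.0, 1,
                                    noise_sd=0.0)
        assert len(detect_strides(acc)) == 100

    def test_device_range_clipping(self):
        from cpts.types import StrideEventSeries
        t0 = np.datetime64("2024-03-04T10:00:00", "ns")
        ts = t0 + (np.arange(10) * 1.1e9).astype("timedelta64[ns]")
        acc = simulate_acceleration(StrideEventSeries(ts), 100.0, 1,
                                    stride_amp_g=10.0)
        assert acc.data.max() == pytest.approx(6.0)
        assert np.all(np.abs(acc.data) <= 6.0)


class TestPressureTrial:
    def test_analytic_pti_closed_form(self):
        # P = 200 kPa, T = 0.6 s -> PTI = 2*200*0.6/pi
        p = fixed_profile(ppp_in_device=200.0,
                          pti_in_device=halfsine_pti(200.0, 0.6))
        tr = simulate_pressure_trial(p, Condition.IN_DEVICE, 1, "insole", 1)
        assert tr.meta["analytic_step_pti"] == pytest.approx(76.3944, abs=1e-3)
        assert tr.meta["stance_duration_s"] == pytest.approx(0.6)

    def test_n_steps_constructed(self):
        from cpts.pressure import detect_stance_phases
        tr = simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                     16, "insole", 1)
        assert len(detect_stance_phases(tr, 34.3)) == 16

    def test_ppp_target_is_exact_max(self):
        p = fixed_profile(ppp_in_device=119.4)
        tr = simulate_pressure_trial(p, Condition.IN_DEVICE, 4, "insole", 1)
        assert tr.frames.max() == pytest.approx(119.4, abs=1e-9)

    def test_dialect_sampling_rates(self):
        tr_i = simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                       1, "insole", 1)
        tr_p = simulate_pressure_trial(fixed_profile(), Condition.NON_DEVICE,
                                       1, "platform", 1)
        assert tr_i.sampling_rate == 50.0 and tr_i.n_sensors == 99
        assert tr_p.sampling_rate == 100.0

    def test_platform_single_contact_rule(self):
        with pytest.raises(ConfigurationError):
            simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                    2, "platform", 1)

    def test_nonpositive_pti_rejected(self):
        with pytest.raises(ConfigurationError):
            fixed_profile(pti_in_device=0.0)


class TestThermalPair:
    @pytest.mark.parametrize("target", [0.66, 1.0, 0.0, -0.4, 2.0])
    def test_roundtrip_exact(self, target):
        p = fixed_profile(tsr_in_device=target)
        pair = simulate_thermal_pair(p, Condition.IN_DEVICE, 1)
        assert thermal_stress_response(pair).value == pytest.approx(
            target, abs=1e-12)

    def test_zero_target_keeps_index_unchanged(self):
        p = fixed_profile(tsr_in_device=0.0)
        pair = simulate_thermal_pair(p, Condition.IN_DEVICE, 1)
        assert pair.index_post == pair.index_pre

    def test_unit_target_equal_relative_change(self):
        p = fixed_profile(tsr_in_device=1.0)
        pair = simulate_thermal_pair(p, Condition.IN_DEVICE, 1)
        assert (pair.index_post / pair.index_pre) == pytest.approx(
            pair.contra_post / pair.contra_pre)

    def test_zero_contra_change_infeasible(self):
        with pytest.raises(InfeasibilityError):
            simulate_thermal_pair(fixed_profile(), Condition.IN_DEVICE, 1,
                                  contra_rel_change=0.0)


class TestGenerateCohort:
    def test_file_counts_and_styles(self, tmp_path):
        man = generate_cohort(4, 9, tmp_path, n_au=2)
        assert len(man.profiles) == 4
        au, nl = man.profiles[0], man.profiles[-1]
        assert (tmp_path / au.id / "thermal.json").exists()
        assert not (tmp_path / nl.id / "thermal.json").exists()
        assert len(list((tmp_path / nl.id).glob(
            "pressure_non_device_trial*.csv"))) == 4
        for p in man.profiles:
            assert (tmp_path / p.id / "strides.csv").exists()
            assert (tmp_path / p.id / "temperature.csv").exists()

    def test_byte_identical_under_seed(self, tmp_path):
        m1 = generate_cohort(2, 5, tmp_path / "a")
        m2 = generate_cohort(2, 5, tmp_path / "b")
        assert m1.digest() == m2.digest()
        for rel in ["manifest.json", f"{m1.profiles[0].id}/strides.csv",
                    f"{m1.profiles[0].id}/temperature.csv",
                    f"{m1.profiles[0].id}/pressure_in_device.csv"]:
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes()

    def test_unique_ids(self, tmp_path):
        man = generate_cohort(3, 1, tmp_path)
        assert len({p.id for p in man.profiles}) == 3
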