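"""Stance segmentation and ulcer-site PPP/PTI against analytic oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpts.errors import InputError, InvalidTrialError, ProtocolError
from cpts.pressure import (RegionMask, StancePhase, detect_stance_phases,
                           select_midgait_steps, step_metrics, trial_summary)
from cpts.synth import (INSOLE_ULCER_SENSOR_IDS, halfsine_pti,
                        simulate_pressure_trial)
from cpts.types import Condition, PressureFrameSeries

from conftest import fixed_profile


def flat_series(frames, fs=100.0, area=1.0):
    """Minimal 2-sensor series from a (n, 2) array of pressures."""
    frames = np.asarray(frames, dtype=float)
    return PressureFrameSeries(
        dialect="insole", sampling_rate=fs,
        times=np.arange(frames.shape[0]) / fs, frames=frames,
        geometry=np.array([[0.0, 0.0], [10.0, 0.0]]),
        sensor_area_cm2=area, sensor_ids=["sensor_000", "sensor_001"])


MASK0 = RegionMask(sensor_ids=["sensor_000"])


class TestDetectStancePhases:
    def test_all_zero_frames_give_no_phases(self):
        s = flat_series(np.zeros((50, 2)))
        assert detect_stance_phases(s, force_threshold_n=10.0) == []

    def test_synthetic_trial_pulse_count(self):
        tr = simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                     16, "insole", 1)
        assert len(detect_stance_phases(tr, 34.3)) == 16

    def test_single_pulse_duration_within_one_sample(self):
        fs, T, P = 50.0, 0.6, 200.0
        t = np.arange(int(2.0 * fs)) / fs
        curve = np.where((t >= 0.5) & (t <= 0.5 + T),
                         P * np.sin(np.pi * np.clip(t - 0.5, 0, T) / T), 0.0)
        s = flat_series(np.column_stack([curve, curve]), fs=fs, area=10.0)
        (phase,) = detect_stance_phases(s, force_threshold_n=30.0)
        assert abs(phase.duration_s - T) <= 1.0 / fs + 1e-9

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            detect_stance_phases(flat_series(np.zeros((0, 2))), 10.0)


class TestSelectMidgaitSteps:
    def _phases(self, n):
        return [StancePhase(i * 10, i * 10 + 5, 0.5) for i in range(n)]

    def test_trim_arithmetic(self):
        assert len(select_midgait_steps(self._phases(16), trim=2)) == 12

    def test_too_few_steps_invalidates_trial(self):
        with pytest.raises(InvalidTrialError) as exc:
            select_midgait_steps(self._phases(15), trim=2, min_steps=12)
        assert exc.value.n_steps == 11

    def test_zero_trim_is_identity(self):
        phases = self._phases(12)
        assert select_midgait_steps(phases, trim=0) == phases


class TestStepMetrics:
    def test_rectangle_oracle(self):
        # constant 100 kPa for exactly 1 s: ppp = 100, pti = 100
        fs = 100.0
        frames = np.zeros((int(fs) + 1, 2))
        frames[:, 0] = 100.0
        s = flat_series(frames, fs=fs)
        ppp, pti = step_metrics(s, StancePhase(0, int(fs) + 1, 1.0), MASK0)
        assert ppp == pytest.approx(100.0)
        assert pti == pytest.approx(100.0)

    def test_halfsine_oracle_at_100hz(self):
        fs, T, P = 100.0, 0.6, 200.0
        t = np.arange(int(T * fs) + 1) / fs
        curve = P * np.sin(np.pi * t / T)
        s = flat_series(np.column_stack([curve, np.zeros_like(curve)]), fs=fs)
        _, pti = step_metrics(s, StancePhase(0, len(t), T), MASK0)
        expected = halfsine_pti(P, T)
        assert abs(pti - expected) / expected < 0.02

    def test_mask_containment(self):
        # non-mask sensor always higher; metrics must ignore it
        frames = np.column_stack([np.full(20, 50.0), np.full(20, 500.0)])
        s = flat_series(frames)
        ppp, pti = step_metrics(s, StancePhase(0, 20, 0.2), MASK0)
        assert ppp == pytest.approx(50.0)

    def test_mask_off_geometry_rejected(self):
        s = flat_series(np.ones((10, 2)))
        with pytest.raises(InputError):
            step_metrics(s, StancePhase(0, 10, 0.1),
                         RegionMask(sensor_ids=["sensor_999"]))


class TestTrialSummary:
    def _two_step_trial(self, pti_target, seed=1):
        p = fixed_profile(pti_non_device=pti_target, ppp_non_device=500.0,
                          study_style="nl")
        return simulate_pressure_trial(p, Condition.NON_DEVICE, 1,
                                       "platform", seed)

    def test_two_step_mean_of_equal_trials(self):
        from cpts.synth import PLATFORM_ULCER_CENTER_MM
        trials = [self._two_step_trial(500.0, s) for s in range(4)]
        mask = RegionMask(center_mm=PLATFORM_ULCER_CENTER_MM)
        summ = trial_summary(trials, mask, protocol="two_step")
        assert summ.pti == pytest.approx(500.0, rel=0.01)

    def test_two_step_mean_reproduces_cohort_value(self):
        # trial PTIs {400, 500, 600, 480.8} average to the published 495.2
        from cpts.synth import PLATFORM_ULCER_CENTER_MM
        trials = [self._two_step_trial(v, s) for s, v in
                  enumerate([400.0, 500.0, 600.0, 480.8])]
        mask = RegionMask(center_mm=PLATFORM_ULCER_CENTER_MM)
        summ = trial_summary(trials, mask, protocol="two_step")
        assert summ.pti == pytest.approx(495.2, rel=0.01)
        assert summ.n_steps_used == 4

    def test_walking_mean_of_equal_steps(self):
        p = fixed_profile(pti_in_device=66.2, ppp_in_device=140.6)
        tr = simulate_pressure_trial(p, Condition.IN_DEVICE, 16, "insole", 1)
        summ = trial_summary(tr, RegionMask(sensor_ids=INSOLE_ULCER_SENSOR_IDS))
        assert summ.n_steps_used == 12          # 16 - 2 trimmed per side
        assert summ.pti == pytest.approx(66.2, rel=0.01)

    def test_two_step_requires_four_trials(self):
        with pytest.raises(ProtocolError):
            trial_summary([self._two_step_trial(500.0)] * 3,
                          RegionMask(sensor_ids=["sensor_000"]),
                          protocol="two_step")

    def test_invalid_walking_trial_propagates(self):
        p = fixed_profile()
        tr = simulate_pressure_trial(p, Condition.IN_DEVICE, 10, "insole", 1)
        with pytest.raises(InvalidTrialError):
            trial_summary(tr, RegionMask(sensor_ids=INSOLE_ULCER_SENSOR_IDS))


class TestInvariants:
    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        """Multiplying all pressures by k multiplies PPP and PTI by k."""
        tr = simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                     3, "insole", 1)
        scaled = PressureFrameSeries(
            dialect=tr.dialect, sampling_rate=tr.sampling_rate,
            times=tr.times, frames=tr.frames * k, geometry=tr.geometry,
            sensor_area_cm2=tr.sensor_area_cm2, sensor_ids=tr.sensor_ids)
        mask = RegionMask(sensor_ids=INSOLE_ULCER_SENSOR_IDS)
        phase = detect_stance_phases(tr, 1.0)[1]
        ppp, pti = step_metrics(tr, phase, mask)
        ppp_k, pti_k = step_metrics(scaled, phase, mask)
        assert ppp_k == pytest.approx(k * ppp, rel=1e-9)
        assert pti_k == pytest.approx(k * pti, rel=1e-9)

    def test_mask_enlargement_monotone(self):
        tr = simulate_pressure_trial(fixed_profile(), Condition.IN_DEVICE,
                                     3, "insole", 1)
        phase = detect_stance_phases(tr, 34.3)[1]
        small = RegionMask(sensor_ids=INSOLE_ULCER_SENSOR_IDS[:1])
        big = RegionMask(sensor_ids=list(tr.sensor_ids))
        ppp_s, pti_s = step_metrics(tr, phase, small)
        ppp_b, pti_b = step_metrics(tr, phase, big)
        assert ppp_b >= ppp_s and pti_b >= pti_s

    def test_halfsine_oracle_at_dialect_rates(self):
        """Generated stances recover 2PT/pi within 2% at 50 and 100 Hz."""
        for dialect, cond in (("insole", Condition.IN_DEVICE),
                              ("platform", Condition.NON_DEVICE)):
            p = fixed_profile(study_style="nl" if dialect == "platform" else "au")
            n = 14 if dialect == "insole" else 1
            tr = simulate_pressure_trial(p, cond, n, dialect, 1)
            expected = tr.meta["analytic_step_pti"]
            if dialect == "insole":
                mask = RegionMask(sensor_ids=INSOLE_ULCER_SENSOR_IDS)
            else:
                from cpts.synth import PLATFORM_ULCER_CENTER_MM
                mask = RegionMask(center_mm=PLATFORM_ULCER_CENTER_MM)
            phase = detect_stance_phases(tr, 34.3)[0]
            _, pti = step_metrics(tr, phase, mask)
            assert abs(pti - expected) / expected <= 0.02
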