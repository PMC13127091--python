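"""Waveform plumbing and transient simulation against closed forms and an
independent adaptive Runge--Kutta oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stimwell import (
    DeviceModel,
    SourceSpec,
    WaveformSpec,
    WellParams,
    charge_summary,
    field_magnitude,
    pulse_width,
    segmentize,
    simulate_cc,
    simulate_vc,
)
from stimwell.protocol import _tile_segments


class TestPulseWidth:
    @pytest.mark.parametrize(
        "f,duty,expected",
        [(100.0, 25.0, 2.5e-3), (100.0, 50.0, 5e-3), (1.0, 100.0, 1.0)],
    )
    def test_values(self, f, duty, expected):
        assert pulse_width(f, duty) == pytest.approx(expected, rel=1e-12)

    def test_zero_frequency_directs_to_dc(self):
        with pytest.raises(ValueError, match="dc"):
            pulse_width(0.0, 25.0)

    def test_width_scales_inversely_with_frequency(self):
        widths = [pulse_width(f, 25.0) for f in (10.0, 100.0, 1000.0)]
        assert widths[0] / widths[1] == pytest.approx(10.0)
        assert widths[1] / widths[2] == pytest.approx(10.0)


class TestSegmentize:
    def test_monophasic(self):
        wf = WaveformSpec(shape="monophasic", amplitude=1.0, frequency=100.0,
                          duty_percent=25.0)
        segs = segmentize(wf)
        assert segs == [(pytest.approx(2.5e-3), 1.0), (pytest.approx(7.5e-3), 0.0)]

    def test_biphasic_symmetric_no_break(self):
        wf = WaveformSpec(shape="biphasic_symmetric", amplitude=1.0,
                          frequency=100.0, duty_percent=25.0)
        segs = segmentize(wf)
        durs = [d for d, _ in segs]
        levels = [v for _, v in segs]
        assert durs == [pytest.approx(2.5e-3)] * 2 + [pytest.approx(5e-3)]
        assert levels == [1.0, -1.0, 0.0]

    def test_dc_single_unbounded_segment(self):
        segs = segmentize(WaveformSpec(shape="dc", amplitude=0.5))
        assert len(segs) == 1
        assert np.isinf(segs[0][0]) and segs[0][1] == 0.5

    def test_periods_sum(self):
        wf = WaveformSpec(shape="biphasic_asymmetric", amplitude=1.0,
                          frequency=50.0, duty_percent=10.0,
                          interphase_break=1e-3)
        assert sum(d for d, _ in segmentize(wf)) == pytest.approx(0.02)

    def test_asymmetric_default_is_charge_balanced(self):
        wf = WaveformSpec(shape="biphasic_asymmetric", amplitude=1.0,
                          frequency=100.0, duty_percent=10.0)
        segs = segmentize(wf)
        balance = sum(d * v for d, v in segs)
        assert balance == pytest.approx(0.0, abs=1e-15)

    def test_overlong_phases_rejected(self):
        with pytest.raises(ValueError, match="period"):
            segmentize(WaveformSpec(shape="biphasic_symmetric", amplitude=1.0,
                                    frequency=100.0, duty_percent=60.0))


class TestSimulateVC:
    def test_step_response_closed_form(self, vc_source, monitor):
        # R_f -> inf: pure RC charging through z_out + r_m + R_e
        well = WellParams(r_e=250.0, r_f=1e14, c_dl=1e-5)
        dev = DeviceModel(well=well, n_wells=1, wiring="parallel")
        wf = WaveformSpec(shape="dc", amplitude=1.0)
        res = simulate_vc(dev, vc_source, monitor, wf, duration=0.01, dt=1e-5)
        r_tot = 50.0 + 50.0 + 250.0
        ref = 1.0 / r_tot * np.exp(-res.t / (r_tot * 1e-5))
        assert np.max(np.abs(res.i_e - ref) / ref.max()) < 1e-9

    def test_dc_steady_state(self, ideal_well, vc_source, monitor):
        dev = DeviceModel(well=ideal_well, n_wells=1, wiring="parallel")
        wf = WaveformSpec(shape="dc", amplitude=1.0)
        res = simulate_vc(dev, vc_source, monitor, wf, duration=0.2, dt=1e-4)
        expected = 1.0 / (50.0 + 50.0 + 250.0 + 1e5)
        assert res.i_e[-1] == pytest.approx(expected, rel=1e-6)

    def test_matches_runge_kutta_oracle(self, ideal_well, vc_source, monitor,
                                        biphasic_1v_100hz):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="parallel")
        duration, dt = 0.03, 1e-5  # 3 periods at 100 Hz
        res = simulate_vc(dev, vc_source, monitor, biphasic_1v_100hz, duration, dt)

        n, c = 8, 1e-5
        r_s = n * (50.0 + 50.0) + 250.0
        r_f = 1e5
        tiles = _tile_segments(segmentize(biphasic_1v_100hz), duration)

        def v_src(t):
            for t0, t1, level in tiles:
                if t < t1:
                    return level
            return tiles[-1][2]

        def rhs(t, y):
            return [((v_src(t) - y[0]) / r_s - y[0] / r_f) / c]

        # integrate segment by segment so the oracle never smooths a step
        vc_ref = np.empty_like(res.t)
        state = [0.0]
        for t0, t1, level in tiles:
            mask = (res.t >= t0 - 1e-12) & (res.t < t1 - 1e-12)
            if t1 >= duration - 1e-12:
                mask = (res.t >= t0 - 1e-12)
            t_eval = res.t[mask]
            sol = solve_ivp(rhs, (t0, t1), state, t_eval=np.clip(t_eval, t0, t1),
                            rtol=1e-11, atol=1e-14, method="RK45")
            vc_ref[mask] = sol.y[0]
            end = solve_ivp(rhs, (t0, t1), state, rtol=1e-11, atol=1e-14)
            state = [end.y[0][-1]]
        i_ref = (res.v_source - vc_ref) / r_s
        scale = np.abs(i_ref).max()
        assert np.max(np.abs(res.i_e - i_ref)) / scale < 1e-8

    def test_current_decays_within_constant_segment(self, ideal_well, vc_source,
                                                    monitor):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="parallel")
        wf = WaveformSpec(shape="monophasic", amplitude=1.0, frequency=100.0,
                          duty_percent=50.0)
        res = simulate_vc(dev, vc_source, monitor, wf, duration=0.01, dt=1e-6)
        on = (res.t > 1e-6) & (res.t < 5e-3 - 1e-6)
        assert np.all(np.diff(np.abs(res.i_e[on])) <= 1e-15)

    def test_compliance_violation_flagged_not_fatal(self, ideal_well, monitor):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="parallel")
        src = SourceSpec(mode="voltage_controlled", z_output=50.0, i_max=1e-6)
        wf = WaveformSpec(shape="dc", amplitude=1.0)
        with pytest.warns(UserWarning, match="compliance"):
            res = simulate_vc(dev, src, monitor, wf, duration=0.01, dt=1e-4)
        assert res.meta["compliance_ok"] is False

    def test_wiring_mismatch_rejected(self, series_device, vc_source, monitor):
        wf = WaveformSpec(shape="dc", amplitude=1.0)
        with pytest.raises(ValueError, match="parallel"):
            simulate_vc(series_device, vc_source, monitor, wf, 0.01, 1e-4)

    def test_energy_sanity(self, parallel_device, vc_source, monitor,
                           biphasic_1v_100hz):
        # R_m dissipation is non-negative, and the energy the source has
        # delivered always covers what R_m has burned (the rest sits in the
        # double layer or other resistors)
        from scipy.integrate import cumulative_trapezoid

        res = simulate_vc(parallel_device, vc_source, monitor, biphasic_1v_100hz,
                          duration=0.02, dt=1e-5)
        p_rm = res.i_total**2 * monitor.r_m
        assert np.all(p_rm >= 0.0)
        e_source = cumulative_trapezoid(res.v_source * res.i_total, res.t, initial=0.0)
        e_rm = cumulative_trapezoid(p_rm, res.t, initial=0.0)
        assert np.all(e_source - e_rm >= -1e-12)


class TestSimulateCC:
    def test_ideal_capacitor_linear_ramp(self, cc_source):
        well = WellParams(r_e=250.0, r_f=1e14, c_dl=1e-5)
        dev = DeviceModel(well=well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="dc", amplitude=1e-3)
        res = simulate_cc(dev, cc_source, wf, duration=5e-3, dt=1e-6)
        vc = res.v_well - res.i_e * 250.0
        ref = 1e-3 * res.t / 1e-5
        assert np.max(np.abs(vc - ref)) / ref.max() < 1e-9

    def test_finite_rf_exponential_build_up(self, ideal_well, cc_source):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="dc", amplitude=1e-3)
        res = simulate_cc(dev, cc_source, wf, duration=0.01, dt=1e-5)
        vc = res.v_well - res.i_e * ideal_well.r_e
        ref = 1e-3 * 1e5 * (1.0 - np.exp(-res.t / (1e5 * 1e-5)))
        assert np.max(np.abs(vc - ref)) / ref.max() < 1e-9

    def test_balanced_biphasic_periodic_steady_state(self, cc_source):
        well = WellParams(r_e=250.0, r_f=1e14, c_dl=1e-5)
        dev = DeviceModel(well=well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="biphasic_symmetric", amplitude=1e-3,
                          frequency=100.0, duty_percent=25.0)
        res = simulate_cc(dev, cc_source, wf, duration=0.1, dt=1e-5)
        vc = res.v_well - res.i_e * 250.0
        period_samples = int(round(0.01 / 1e-5))
        # after several periods, V_c is periodic: value at period start repeats
        v_starts = vc[::period_samples]
        assert abs(v_starts[-1] - v_starts[-2]) < 1e-9 * max(1.0, np.abs(vc).max())

    def test_v_well_monotone_toward_asymptote(self, ideal_well, cc_source):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="dc", amplitude=1e-3)
        res = simulate_cc(dev, cc_source, wf, duration=0.05, dt=1e-4)
        assert np.all(np.diff(res.v_well) >= -1e-15)
        assert res.v_well[-1] <= 1e-3 * (250.0 + 1e5) + 1e-9

    def test_voltage_compliance_flagged(self, ideal_well):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="series")
        src = SourceSpec(mode="current_controlled", v_max=1.0)
        wf = WaveformSpec(shape="dc", amplitude=1e-3)
        with pytest.warns(UserWarning, match="compliance"):
            res = simulate_cc(dev, src, wf, duration=0.05, dt=1e-4)
        assert res.meta["compliance_ok"] is False


class TestChargeSummary:
    def test_full_relaxation_leaves_no_residual_charge(self, vc_source, monitor):
        # period >> tau and R_f -> inf: every pulse's charge is recovered
        well = WellParams(r_e=250.0, r_f=1e14, c_dl=1e-7)  # tau = 25 us
        dev = DeviceModel(well=well, n_wells=1, wiring="parallel")
        wf = WaveformSpec(shape="monophasic", amplitude=1.0, frequency=10.0,
                          duty_percent=50.0)
        res = simulate_vc(dev, vc_source, monitor, wf, duration=0.2, dt=1e-6)
        cs = charge_summary(res, wf)
        assert np.all(np.abs(cs.q_acc) / cs.q_inj < 1e-3)

    def test_cc_symmetric_biphasic_balances_exactly(self, ideal_well, cc_source):
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="biphasic_symmetric", amplitude=1e-3,
                          frequency=100.0, duty_percent=25.0)
        res = simulate_cc(dev, cc_source, wf, duration=0.05, dt=1e-6)
        cs = charge_summary(res, wf)
        assert np.allclose(cs.q_acc, 0.0, atol=1e-15)

    def test_constant_current_trapezoid(self, cc_source, ideal_well):
        # 1 mA for 2.5 ms injects 2.5 uC
        dev = DeviceModel(well=ideal_well, n_wells=8, wiring="series")
        wf = WaveformSpec(shape="monophasic", amplitude=1e-3, frequency=100.0,
                          duty_percent=25.0)
        res = simulate_cc(dev, cc_source, wf, duration=0.01, dt=1e-6)
        cs = charge_summary(res, wf)
        assert cs.q_inj[0] == pytest.approx(2.5e-6, rel=1e-3)

    def test_dc_reports_cumulative_only(self, ideal_well, vc_source, monitor):
        dev = DeviceModel(well=ideal_well, n_wells=1, wiring="parallel")
        wf = WaveformSpec(shape="dc", amplitude=1.0)
        res = simulate_vc(dev, vc_source, monitor, wf, duration=0.01, dt=1e-5)
        cs = charge_summary(res, wf)
        assert cs.q_inj.size == 0 and cs.q_rec.size == 0
        assert cs.q_total == pytest.approx(res.q_cum[-1])


class TestFieldMagnitude:
    def test_one_volt_over_ten_mm(self):
        # V_e = 1 V across d = 10 mm reads 100 mV/mm
        assert field_magnitude(np.array([4e-3]), 250.0, 10.0)[0] == pytest.approx(100.0)

    def test_safe_limit_field(self):
        # 1.3 V over 10 mm: 130 mV/mm
        assert field_magnitude(np.array([1.3 / 250.0]), 250.0, 10.0)[0] == pytest.approx(130.0)

    def test_zero_current_zero_field(self):
        assert field_magnitude(np.zeros(5), 250.0, 10.0) == pytest.approx(np.zeros(5))
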