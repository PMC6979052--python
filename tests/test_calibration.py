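"""Nernst potentials, potassium bookkeeping, plateau extraction,
calibration fitting and Em estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from empredict.calibration import (
    GAS_CONSTANT,
    FARADAY_CONSTANT,
    AdditionEvent,
    CalibrationCurve,
    FluorescenceTrace,
    IonicContext,
    build_calibration,
    cumulative_potassium,
    detect_plateaus,
    estimate_em,
    nernst_potential,
    process_trace,
)
from empredict.errors import (
    DegenerateFitError,
    FlatCalibrationError,
    InsufficientCalibrationError,
    InvalidInputError,
    TraceInvariantError,
    WindowTooShortError,
)
from empredict.synthetic import DyeModel, simulate_trace

T_BODY = 310.15


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_potential(120, 120, T_BODY) == 0.0

    def test_htf_potassium_equilibrium(self):
        # closed form: (R*T/F) * ln(5/120) * 1000, R=8.314, F=96485
        expected = GAS_CONSTANT * T_BODY / FARADAY_CONSTANT * math.log(5.0 / 120.0) * 1e3
        assert nernst_potential(5.0, 120.0, T_BODY) == pytest.approx(expected)
        assert nernst_potential(5.0, 120.0, T_BODY) == pytest.approx(-84.95, abs=0.05)

    def test_doubling_adds_rtf_ln2(self):
        step = nernst_potential(10, 120, T_BODY) - nernst_potential(5, 120, T_BODY)
        assert step == pytest.approx(
            GAS_CONSTANT * T_BODY / FARADAY_CONSTANT * math.log(2) * 1e3, abs=1e-9
        )
        assert step == pytest.approx(18.53, abs=0.01)

    @pytest.mark.parametrize("bad", [(0, 120, T_BODY), (5, -1, T_BODY), (5, 120, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            nernst_potential(*bad)

    @given(
        k1=st.floats(0.5, 200), k2=st.floats(0.5, 200),
        k_in=st.floats(50, 200), temp=st.floats(270, 320),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_antisymmetric_temperature_linear(self, k1, k2, k_in, temp):
        e1 = nernst_potential(k1, k_in, temp)
        e2 = nernst_potential(k2, k_in, temp)
        if k1 < k2:
            assert e1 < e2
        # swapping in/out flips the sign
        assert nernst_potential(k_in, k1, temp) == pytest.approx(-e1, abs=1e-9)
        # linear in absolute temperature
        assert nernst_potential(k1, k_in, 2 * temp) == pytest.approx(2 * e1, rel=1e-12)


class TestCumulativePotassium:
    def test_single_aliquot_mass_balance(self, context):
        events = [
            AdditionEvent(10, "valinomycin"),
            AdditionEvent(20, "KCl", aliquot_volume=10, aliquot_concentration=1000),
        ]
        out = cumulative_potassium(context, events, initial_volume=2.0)
        # (5*2 + 1000*0.01) / 2.01 by hand
        assert out[0] == (10, 5.0, 2.0)  # valinomycin leaves K unchanged
        assert out[1][1] == pytest.approx(20.0 / 2.01, abs=1e-12)
        assert out[1][1] == pytest.approx(9.95, abs=0.01)
        assert out[1][2] == pytest.approx(2.010)

    def test_zero_volume_addition_is_noop(self, context):
        events = [AdditionEvent(5, "KCl", aliquot_volume=0, aliquot_concentration=1000)]
        out = cumulative_potassium(context, events, 2.0)
        assert out[0][1] == 5.0 and out[0][2] == 2.0

    def test_successive_additions_dilute(self, context):
        events = [
            AdditionEvent(1, "KCl", aliquot_volume=20, aliquot_concentration=1000),
            AdditionEvent(2, "KCl", aliquot_volume=20, aliquot_concentration=1000),
        ]
        out = cumulative_potassium(context, events, 2.0)
        first_increment = out[0][1] - 5.0
        naive_second = out[0][1] + first_increment
        assert out[1][1] < naive_second  # growing volume dilutes the second step

    @given(
        volumes=st.lists(st.floats(1, 100), min_size=1, max_size=6),
        conc=st.floats(100, 3000),
        v0=st.floats(1.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mole_conservation(self, volumes, conc, v0):
        context = IonicContext()
        events = [
            AdditionEvent(float(i + 1), "KCl", aliquot_volume=v, aliquot_concentration=conc)
            for i, v in enumerate(volumes)
        ]
        out = cumulative_potassium(context, events, v0)
        moles = context.k_out_initial * v0
        for (_, k, vol), ev in zip(out, events):
            moles += ev.aliquot_concentration * ev.aliquot_volume / 1000.0
            assert k * vol == pytest.approx(moles, rel=1e-9)

    def test_negative_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            AdditionEvent(1, "KCl", aliquot_volume=-1, aliquot_concentration=1000)


class TestTraceInvariants:
    def test_kcl_before_valinomycin_rejected(self):
        with pytest.raises(TraceInvariantError):
            FluorescenceTrace(
                time=np.arange(100.0),
                fluorescence=np.full(100, 50.0),
                events=[
                    AdditionEvent(10, "KCl", 10, 1000),
                    AdditionEvent(20, "valinomycin"),
                ],
            )

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(TraceInvariantError):
            FluorescenceTrace(
                time=np.array([0.0, 1.0, 1.0, 2.0]),
                fluorescence=np.ones(4), events=[],
            )

    def test_event_outside_span_rejected(self):
        with pytest.raises(TraceInvariantError):
            FluorescenceTrace(
                time=np.arange(10.0), fluorescence=np.ones(10),
                events=[AdditionEvent(50, "valinomycin")],
            )


class TestDetectPlateaus:
    def test_noiseless_steps_recovered_exactly(self, step_trace_factory):
        trace = step_trace_factory([100, 80, 90, 95])
        plateaus = detect_plateaus(trace, window=20, settle_delay=10)
        assert [p["fluorescence"] for p in plateaus] == [100, 80, 90, 95]
        assert plateaus[0]["event"] is None
        assert all(p["sd"] == 0 for p in plateaus)

    def test_noisy_plateau_means_within_sem(self, step_trace_factory):
        # window of 20 s at 2 Hz covers ~41 samples; 3 SEM tolerance
        trace = step_trace_factory([100, 80, 90, 95], noise_sd=1.0, seed=42)
        plateaus = detect_plateaus(trace, window=20, settle_delay=10)
        n_window = 41
        for p, truth in zip(plateaus, [100, 80, 90, 95]):
            assert p["fluorescence"] == pytest.approx(truth, abs=3 / np.sqrt(n_window))

    def test_event_too_close_to_end_raises(self, step_trace_factory):
        trace = step_trace_factory([100, 80], segment_s=25)  # needs 30 s after event
        with pytest.raises(WindowTooShortError):
            detect_plateaus(trace, window=20, settle_delay=10)


class TestBuildCalibration:
    def _plateaus_from_line(self, context, slope, intercept, n_kcl=3):
        events = [AdditionEvent(60, "valinomycin")]
        for i in range(n_kcl):
            events.append(AdditionEvent(
                120 + 60 * i, "KCl", aliquot_volume=20 * (i + 1),
                aliquot_concentration=1000,
            ))
        k_after = cumulative_potassium(context, events, 2.0)
        plateaus = [{"event": None, "fluorescence": 0.0, "sd": 0.0}]
        for ev, (_, k, _) in zip(events, k_after):
            k_eff = context.k_out_initial if ev.kind == "valinomycin" else k
            em = nernst_potential(k_eff, context.k_in, context.temperature)
            plateaus.append({
                "event": ev, "fluorescence": intercept + slope * em, "sd": 0.0,
            })
        return plateaus, events

    def test_exact_line_recovered(self, context):
        plateaus, events = self._plateaus_from_line(context, 1.5, 200.0)
        curve = build_calibration(plateaus, context, events, 2.0)
        assert curve.slope == pytest.approx(1.5, abs=1e-9)
        assert curve.intercept == pytest.approx(200.0, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_fit_exactly(self, context):
        plateaus, events = self._plateaus_from_line(context, 2.0, 100.0, n_kcl=1)
        curve = build_calibration(plateaus, context, events, 2.0)
        assert len(curve.points) == 2
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_perturbed_point_matches_hand_ols(self, context):
        plateaus, events = self._plateaus_from_line(context, 1.5, 200.0)
        plateaus[2]["fluorescence"] += 5.0
        curve = build_calibration(plateaus, context, events, 2.0)
        em = np.array([p[0] for p in curve.points])
        afu = np.array([p[1] for p in curve.points])
        # closed-form OLS on the 4 points
        b = np.cov(em, afu, ddof=0)[0, 1] / np.var(em)
        a = afu.mean() - b * em.mean()
        assert curve.slope == pytest.approx(b, rel=1e-9)
        assert curve.intercept == pytest.approx(a, rel=1e-9)
        assert curve.r_squared < 1.0
        residuals = afu - (curve.intercept + curve.slope * em)
        assert np.sum(residuals * em) == pytest.approx(0.0, abs=1e-6)

    def test_insufficient_points_raise(self, context):
        plateaus, events = self._plateaus_from_line(context, 1.5, 200.0, n_kcl=1)
        # drop the KCl plateau; only the valinomycin anchor remains
        with pytest.raises(InsufficientCalibrationError):
            build_calibration(plateaus[:2], context, events[:1], 2.0)


class TestEstimateEm:
    @pytest.fixture
    def exact_curve(self):
        ems = [-84.9, -60.0, -40.0, -20.0]
        return CalibrationCurve(
            points=[(em, 200 + 1.5 * em) for em in ems],
            slope=1.5, intercept=200.0, r_squared=1.0,
        )

    def test_calibration_point_maps_to_its_potential(self, exact_curve):
        em, fl = exact_curve.points[1]
        assert estimate_em(fl, exact_curve).em == pytest.approx(em, abs=1e-9)

    def test_midpoint_maps_to_mean_potential(self, exact_curve):
        (em1, f1), (em2, f2) = exact_curve.points[1:3]
        result = estimate_em((f1 + f2) / 2, exact_curve)
        assert result.em == pytest.approx((em1 + em2) / 2, abs=1e-9)

    def test_piecewise_mode_agrees_on_linear_curve(self, exact_curve):
        for fl in [80.0, 140.0, 175.0]:
            lin = estimate_em(fl, exact_curve, mode="linear").em
            pw = estimate_em(fl, exact_curve, mode="piecewise").em
            assert lin == pytest.approx(pw, abs=1e-9)

    def test_extrapolation_flagged(self, exact_curve):
        fl_values = [p[1] for p in exact_curve.points]
        assert estimate_em(min(fl_values) - 10, exact_curve).extrapolated
        assert not estimate_em(np.mean(fl_values), exact_curve).extrapolated

    def test_flat_curve_raises(self):
        curve = CalibrationCurve(points=[(-80, 100), (-40, 100)],
                                 slope=0.0, intercept=100.0, r_squared=0.0)
        with pytest.raises(FlatCalibrationError):
            estimate_em(100.0, curve)


class TestProcessTrace:
    def test_noise_free_round_trip(self, context):
        trace = simulate_trace(-60.0, dye=DyeModel(equilibration_tau=0.5),
                               context=context)
        m = process_trace(trace, context)
        assert m.em == pytest.approx(-60.0, abs=0.1)
        assert m.curve_r_squared > 0.9999
        assert not m.extrapolated

    def test_cap_group_mean_round_trip(self, context):
        trace = simulate_trace(-57.8, dye=DyeModel(equilibration_tau=0.5),
                               context=context)
        assert process_trace(trace, context).em == pytest.approx(-57.8, abs=0.1)

    def test_no_kcl_events_raises(self, step_trace_factory):
        trace = step_trace_factory([100, 80], event_kinds=["valinomycin"])
        with pytest.raises(InsufficientCalibrationError):
            process_trace(trace)

    def test_batch_preserves_order(self, context):
        from empredict.calibration import process_traces

        truths = [-70.0, -50.0, -30.0]
        traces = [
            simulate_trace(em, dye=DyeModel(equilibration_tau=0.5), context=context)
            for em in truths
        ]
        results = process_traces(traces, context)
        assert len(results) == 3
        for m, em in zip(results, truths):
            assert m.em == pytest.approx(em, abs=0.1)

    @given(
        em=st.floats(-90, -20),
        gain=st.floats(0.2, 5.0),
        offset=st.floats(-50, 200),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_fluorescence_invariance(self, em, gain, offset):
        """Internal calibration cancels gain/offset changes in AFU."""
        context = IonicContext()
        trace = simulate_trace(em, dye=DyeModel(equilibration_tau=0.5),
                               context=context)
        rescaled = FluorescenceTrace(
            time=trace.time,
            fluorescence=np.maximum(gain * trace.fluorescence + offset, 1e-6),
            events=trace.events,
            initial_volume=trace.initial_volume,
        )
        if np.any(gain * trace.fluorescence + offset <= 0):
            return  # clipping would break affinity; out of scope
        m0 = process_trace(trace, context)
        m1 = process_trace(rescaled, context)
        assert m1.em == pytest.approx(m0.em, abs=1e-6)
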