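"""Sensor characterization: sensitivity, noise, LOD, functionality,
transient kinetics, and implant geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fscvkit import (
    EvokedConfig,
    FlowCellConfig,
    NoTransientError,
    axial_stiffness,
    bolus_peak_currents,
    classify_sensor,
    compute_lod,
    cross_section_area,
    fit_sensitivity,
    flexural_rigidity,
    noise_rms,
    simulate_evoked_session,
    simulate_fault_session,
    simulate_flowcell_session,
    transient_metrics,
)
from fscvkit.chemometrics import ConcentrationTrace
from fscvkit.metrics import CARBON_FIBER_E_GPA, SILICA_E_GPA


class TestSensitivity:
    def test_noiseless_points_recover_slope_and_unity_r(self):
        concs = np.array([0.25, 0.5, 1.0])
        currents = 51.96 * concs
        fit = fit_sensitivity(concs, currents)
        assert fit.slope == pytest.approx(51.96)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_normalized_sensitivity_from_printed_values(self):
        # slope 51.96 nA/uM with 904 nA background -> 5.75e-5 nA nM^-1 nA^-1
        concs = np.array([0.25, 0.5, 1.0])
        fit = fit_sensitivity(concs, 51.96 * concs, background_current_nA=904.0)
        assert fit.normalized_slope == pytest.approx(5.748e-5, rel=1e-3)

    def test_flat_response_flagged_undefined(self):
        fit = fit_sensitivity(np.array([0.25, 0.5, 1.0]), np.array([5.0, 5.0, 5.0]))
        assert fit.slope == 0.0
        assert not fit.r_defined

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_sensitivity(np.array([0.5, 0.5]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_sensitivity(np.array([0.25, 0.5]), np.array([1.0, 2.0]),
                            background_current_nA=0.0)

    def test_slope_recovery_from_synthetic_flowcell(self, waveform):
        from fscvkit import TemplateSpec

        spec = TemplateSpec(sensitivity_slope=51.96)
        session, truth = simulate_flowcell_session(
            FlowCellConfig(seed=14), spec, waveform
        )
        concs, currents = bolus_peak_currents(session, truth["boluses"])
        fit = fit_sensitivity(concs, currents)
        assert fit.slope == pytest.approx(51.96, rel=0.05)
        assert fit.pearson_r > 0.99


class TestNoise:
    def test_zero_trace_has_zero_rms(self):
        assert noise_rms(np.zeros(100)) == 0.0

    def test_white_noise_rms_estimator_consistent(self, rng):
        x = rng.normal(0.0, 0.1, 10_000)
        assert noise_rms(x) == pytest.approx(0.1, abs=0.005)

    def test_chronic_generator_noise_level(self, waveform, template_spec):
        session, _ = simulate_evoked_session(
            EvokedConfig(current_noise_rms=0.04, drift_rate=0.0, seed=21),
            template_spec, waveform,
        )
        rows = session.currents[:20]
        residual = rows - rows.mean(axis=0)
        assert noise_rms(residual.ravel()) == pytest.approx(0.04, rel=0.05)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            noise_rms(np.zeros(5))


class TestLod:
    def test_reported_chronic_noise_implies_lod(self):
        assert compute_lod(1.9) == pytest.approx(5.7)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_lod_is_exactly_three_times_noise(self, noise):
        assert compute_lod(noise) == 3.0 * noise

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            compute_lod(-1.0)


class TestClassifySensor:
    @pytest.mark.parametrize(
        "mode,reason",
        [("perforated", "high_noise"), ("broken", "low_background"),
         ("saturated", "saturation")],
    )
    def test_fault_sessions_report_matching_reason(self, waveform, mode, reason):
        status = classify_sensor(simulate_fault_session(mode, waveform, seed=2))
        assert status.reason == reason
        assert not status.functional

    def test_healthy_flowcell_session_is_functional(self, waveform, template_spec):
        session, _ = simulate_flowcell_session(
            FlowCellConfig(seed=3), template_spec, waveform
        )
        status = classify_sensor(session)
        assert status.functional and status.reason == "none"
        assert status.noise_rms_nA < 1.0
        assert status.max_background_nA > 100.0


def exponential_trace(tau_s, peak=400.0, rep_freq=10.0, n=120, peak_idx=20,
                      noise=1.0):
    times = np.arange(n) / rep_freq
    dda = np.zeros(n)
    dda[:peak_idx] = 0.0
    after = times[peak_idx:] - times[peak_idx]
    dda[peak_idx:] = peak * np.exp(-after / tau_s)
    return ConcentrationTrace(dda_nM=dda, scan_times=times, noise_rms_nM=noise,
                              background_window=(0, peak_idx))


class TestTransientMetrics:
    def test_sampled_exponential_recovers_tau_ln2(self):
        tm = transient_metrics(exponential_trace(0.150))
        assert tm.decay_half_time_ms == pytest.approx(150.0 * math.log(2), abs=5.0)

    def test_published_mean_decay_back_solved_tau(self):
        # tau = 119 / ln 2 = 171.7 ms reproduces a 119 ms half decay
        tm = transient_metrics(exponential_trace(0.1717))
        assert tm.decay_half_time_ms == pytest.approx(119.0, abs=5.0)

    @pytest.mark.parametrize("tau", [0.150, 0.1717, 0.250, 0.350])
    def test_interpolation_error_bounded(self, tau):
        tm = transient_metrics(exponential_trace(tau))
        assert tm.decay_half_time_ms == pytest.approx(tau * 1e3 * math.log(2), abs=5.0)

    def test_flat_trace_raises_no_transient(self):
        trace = ConcentrationTrace(
            dda_nM=np.zeros(50), scan_times=np.arange(50) / 10.0,
            noise_rms_nM=1.0, background_window=(0, 10),
        )
        with pytest.raises(NoTransientError):
            transient_metrics(trace)

    def test_trace_never_halving_flagged_undefined(self):
        dda = np.concatenate([np.zeros(10), np.full(40, 300.0)])
        trace = ConcentrationTrace(
            dda_nM=dda, scan_times=np.arange(50) / 10.0, noise_rms_nM=1.0,
            background_window=(0, 10),
        )
        tm = transient_metrics(trace)
        assert tm.peak_dDA_nM == pytest.approx(300.0)
        assert not tm.decay_defined


class TestGeometry:
    def test_published_cross_sections(self):
        assert round(cross_section_area(90.0)) == 6362
        assert round(cross_section_area(125.0)) == 12272

    def test_unit_area_closed_form(self):
        assert cross_section_area(2.0 / math.sqrt(math.pi)) == pytest.approx(1.0)

    def test_area_ratio_exceeds_hundredfold(self):
        # CFE shaft area vs the stated maximal probe area of ~60 um^2
        assert cross_section_area(90.0) / 60.0 >= 100.0

    def test_rigidity_reproduces_published_bounds(self):
        cfe = flexural_rigidity(90.0, SILICA_E_GPA)
        assert cfe == pytest.approx(2.3e-7, rel=0.01)
        uip = flexural_rigidity(7.0, CARBON_FIBER_E_GPA)
        assert uip < 8e-11

    @given(st.floats(min_value=1.0, max_value=500.0))
    @settings(max_examples=50, derandomize=True)
    def test_scaling_laws(self, d):
        assert cross_section_area(2 * d) == pytest.approx(4 * cross_section_area(d))
        assert flexural_rigidity(2 * d, 72.0) == pytest.approx(
            16 * flexural_rigidity(d, 72.0)
        )

    def test_axial_stiffness_scale_of_stimulation_electrode(self):
        # ~125 um Pt/Ir electrode over a few mm gives hundreds of kN/m
        k = axial_stiffness(125.0, 168.0, 5.5)
        assert 2e5 < k < 6e5

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cross_section_area(0.0)
        with pytest.raises(ValueError):
            flexural_rigidity(10.0, -1.0)
        with pytest.raises(ValueError):
            axial_stiffness(10.0, 72.0, 0.0)
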