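"""Tests of the event-driven TM model simulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stpfit import (
    ParameterError,
    PeakSeries,
    StimTrain,
    TMParameters,
    render_trace,
    simulate_continuous,
    simulate_discrete,
)
from stpfit.model import (
    continuous_peak_values,
    discrete_states,
    double_exponential_kernel,
    kernel_peak_time,
    peak_values,
)

param_sets = st.builds(
    TMParameters,
    f=st.floats(0.0, 1.0),
    U=st.floats(0.0, 1.0),
    F=st.floats(1e-3, 5.0),
    D=st.floats(1e-3, 5.0),
    A=st.floats(0.1, 10.0),
    tau_syn=st.floats(1e-3, 0.02),
)


class TestDiscreteMap:
    def test_invalid_parameters_name_the_violated_bound(self):
        with pytest.raises(ParameterError, match="f="):
            TMParameters(f=1.5, U=0.2, F=0.5, D=0.2)
        with pytest.raises(ParameterError, match="D > 0"):
            TMParameters(f=0.1, U=0.2, F=0.5, D=0.0)

    def test_no_facilitation_keeps_utilization_at_baseline(self):
        p = TMParameters(f=0.0, U=0.4, F=1.0, D=0.2)
        u, _, _ = discrete_states(p, StimTrain(frequency=20.0, n_pulses=10))
        assert np.allclose(u, 0.4)

    def test_first_pulse_closed_form(self):
        # theta = [F, D, f, U] = [2, 0.05, 0.1, 0]: I[1] = A*(f + (1-f)*U)
        p = TMParameters(f=0.1, U=0.0, F=2.0, D=0.05)
        series = simulate_discrete(p, StimTrain(frequency=50.0, n_pulses=1))
        assert series.peaks[0] == pytest.approx(0.1, abs=1e-15)

    def test_empty_train_gives_empty_series(self, reference_params):
        series = simulate_discrete(
            reference_params, StimTrain(frequency=20.0, n_pulses=0)
        )
        assert len(series) == 0

    @pytest.mark.parametrize("frequency", [20.0, 50.0])
    def test_matches_event_driven_continuous_solution(
        self, reference_params, frequency
    ):
        n = 30
        discrete = peak_values(reference_params, frequency, n)
        stim = np.arange(1, n + 1) / frequency
        continuous = continuous_peak_values(reference_params, stim)
        assert np.allclose(discrete, continuous, rtol=1e-9)

    def test_peak_scales_linearly_in_A(self, rng):
        for _ in range(20):
            p = TMParameters(
                f=rng.uniform(0, 1), U=rng.uniform(0, 1),
                F=rng.uniform(0.01, 2), D=rng.uniform(0.01, 2),
                A=rng.uniform(0.1, 10),
            )
            scaled = peak_values(p, 30.0, 40)
            unit = peak_values(p.replace(A=1.0), 30.0, 40)
            assert np.allclose(scaled, p.A * unit, rtol=0, atol=1e-12 * p.A)

    def test_fast_recovery_limit_without_facilitation(self):
        # f = 0 and D -> 0: resources fully recover between pulses, so
        # R[n] ~ 1 and I[n] = I[n-1]*exp(-1/(10*tau)) + A*U
        p = TMParameters(f=0.0, U=0.3, F=0.5, D=1e-6, A=2.0, tau_syn=0.003)
        u, R, I = discrete_states(p, StimTrain(frequency=10.0, n_pulses=20))
        assert np.allclose(R, 1.0, atol=1e-12)
        decay = np.exp(-1.0 / (10.0 * p.tau_syn))
        expected = np.empty(20)
        prev = 0.0
        for i in range(20):
            prev = prev * decay + p.A * p.U
            expected[i] = prev
        assert np.allclose(I, expected, rtol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(params=param_sets, frequency=st.floats(1.0, 200.0))
    def test_state_bounds(self, params, frequency):
        u, R, _ = discrete_states(params, StimTrain(frequency=frequency, n_pulses=60))
        lower = min(params.U, params.f + (1 - params.f) * params.U)
        assert np.all(u >= lower - 1e-12) and np.all(u <= 1.0 + 1e-12)
        assert np.all(R >= -1e-12) and np.all(R <= 1.0 + 1e-12)


class TestContinuousSimulation:
    def test_no_pulses_is_flat_zero(self, reference_params):
        trace = simulate_continuous(reference_params, [], dt=1e-3)
        assert np.all(trace.current == 0.0)

    def test_single_pulse_decays_exponentially(self, reference_params):
        trace = simulate_continuous(reference_params, [0.1], dt=1e-4, t_end=0.2)
        after = trace.times > 0.1
        t0 = trace.times[after][0]
        i0 = trace.current[after][0]
        expected = i0 * np.exp(-(trace.times[after] - t0) / reference_params.tau_syn)
        assert np.allclose(trace.current[after], expected, rtol=1e-9)

    def test_unsorted_stim_times_rejected(self, reference_params):
        with pytest.raises(ValueError, match="increasing"):
            simulate_continuous(reference_params, [0.2, 0.1], dt=1e-4)

    def test_coarse_grid_warns_but_peaks_stay_exact(self, reference_params, caplog):
        stim = np.arange(1, 11) / 100.0
        with caplog.at_level("WARNING", logger="stpfit.model"):
            simulate_continuous(reference_params, stim, dt=0.05)
        assert any("undersamples" in r.message for r in caplog.records)
        assert np.allclose(
            continuous_peak_values(reference_params, stim),
            peak_values(reference_params, 100.0, 10),
            rtol=1e-9,
        )


class TestRenderTrace:
    def test_single_peak_reaches_amplitude_at_kernel_peak_time(self):
        series = PeakSeries(frequency=1.0, peaks=[2.0])
        tr, td = 0.001, 0.010
        trace = render_trace(series, (tr, td), dt=1e-5)
        assert trace.current.max() == pytest.approx(2.0, rel=1e-3)
        t_max = trace.times[np.argmax(trace.current)]
        assert t_max - 1.0 == pytest.approx(kernel_peak_time(tr, td), abs=2e-5)

    def test_empty_series_renders_zero(self):
        trace = render_trace(PeakSeries(frequency=10.0, peaks=[]), (0.001, 0.01))
        assert np.all(trace.current == 0.0)

    def test_degenerate_kernel_rejected(self):
        series = PeakSeries(frequency=10.0, peaks=[1.0])
        with pytest.raises(ValueError, match="kernel"):
            render_trace(series, (0.01, 0.01))

    def test_overlapping_kernels_superpose_linearly(self):
        # pulses 5 ms apart with tau_decay = 10 ms: direct summation oracle
        series = PeakSeries(frequency=200.0, peaks=[1.0, 0.7])
        tr, td = 0.0005, 0.010
        trace = render_trace(series, (tr, td), dt=1e-5)
        stim = np.array([1, 2]) / 200.0
        oracle = np.zeros_like(trace.times)
        for t_pulse, amp in zip(stim, [1.0, 0.7]):
            oracle += amp * double_exponential_kernel(trace.times - t_pulse, tr, td)
        assert np.allclose(trace.current, oracle, atol=1e-12)
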