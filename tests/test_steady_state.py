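"""Tests of the closed-form steady state and its trust-region fitter."""

import numpy as np
import pytest

from stpfit import (
    SteadyStateFitter,
    SteadyStateObservations,
    TMParameters,
    fit_steady_state,
    steady_state_cost,
    steady_state_curve,
    steady_state_response,
)
from stpfit.evaluation import parameter_distance
from stpfit.model import peak_values
from stpfit.steady_state import profile_amplitude, steady_state_gradient
from stpfit.synthetic import STANDARD_FREQUENCIES, sample_parameters


class TestSteadyStateResponse:
    def test_no_facilitation_fixes_utilization_at_baseline(self):
        p = TMParameters(f=0.0, U=0.35, F=1.3, D=0.2)
        for freq in (5.0, 50.0, 200.0):
            assert steady_state_response(p, freq).u_inf == pytest.approx(0.35)

    def test_low_frequency_limit(self, reference_params):
        p = reference_params
        r = steady_state_response(p, 0.001)
        assert r.u_inf == pytest.approx(p.f + (1 - p.f) * p.U, abs=1e-6)
        assert r.R_inf == pytest.approx(1.0, abs=1e-6)
        assert r.I_inf == pytest.approx(p.A * (p.f + (1 - p.f) * p.U), abs=1e-6)

    def test_matches_long_discrete_simulation(self, reference_params):
        r = steady_state_response(reference_params, 20.0)
        tail = peak_values(reference_params, 20.0, 500)[-1]
        assert r.I_inf == pytest.approx(tail, rel=1e-8)

    def test_nonpositive_frequency_rejected(self, reference_params):
        with pytest.raises(ValueError):
            steady_state_response(reference_params, 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(10):
            p = sample_parameters(1, seed=int(rng.integers(2**31)))[0]
            freq = float(rng.uniform(5, 200))
            grad = steady_state_gradient(p, freq)[0]
            eps = 1e-7
            for i, name in enumerate(("f", "U", "F", "D", "A")):
                hi = p.replace(**{name: getattr(p, name) + eps})
                lo = p.replace(**{name: getattr(p, name) - eps})
                fd = (
                    steady_state_response(hi, freq).I_inf
                    - steady_state_response(lo, freq).I_inf
                ) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestSteadyStateCost:
    def test_zero_at_generating_parameters(self, reference_params):
        freqs = np.array(STANDARD_FREQUENCIES)
        obs = SteadyStateObservations.from_arrays(
            freqs, steady_state_curve(reference_params, freqs)
        )
        assert steady_state_cost(reference_params, obs) == pytest.approx(0.0, abs=1e-30)

    def test_single_observation_arithmetic(self, reference_params):
        i_model = steady_state_response(reference_params, 20.0).I_inf
        obs = SteadyStateObservations({20.0: i_model + 1.0})
        assert steady_state_cost(reference_params, obs) == pytest.approx(1.0)

    def test_equals_brute_force_sum_at_perturbed_parameters(self, reference_params):
        freqs = np.array(STANDARD_FREQUENCIES)
        obs = SteadyStateObservations.from_arrays(
            freqs, steady_state_curve(reference_params, freqs)
        )
        perturbed = reference_params.replace(f=0.15, D=0.25)
        expected = sum(
            (obs[f] - steady_state_response(perturbed, f).I_inf) ** 2 for f in freqs
        )
        assert steady_state_cost(perturbed, obs) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_frequency_ordering(self, reference_params):
        freqs = np.array(STANDARD_FREQUENCIES)
        amps = steady_state_curve(reference_params, freqs) * 1.07
        fwd = SteadyStateObservations.from_arrays(freqs, amps)
        rev = SteadyStateObservations.from_arrays(freqs[::-1], amps[::-1])
        assert steady_state_cost(reference_params, fwd) == pytest.approx(
            steady_state_cost(reference_params, rev), rel=1e-14
        )


class TestSteadyStateFitter:
    def _obs(self, params, freqs=STANDARD_FREQUENCIES):
        freqs = np.array(freqs, dtype=float)
        return SteadyStateObservations.from_arrays(
            freqs, steady_state_curve(params, freqs)
        )

    def test_fit_from_truth_stays_at_truth(self, reference_params):
        params, traj = fit_steady_state(
            self._obs(reference_params), init=reference_params
        )
        assert traj[-1] <= 1e-12
        assert np.allclose(
            params.as_vector(), reference_params.as_vector(), rtol=1e-4
        )

    def test_fit_from_random_init_reproduces_curve(self, reference_params):
        obs = self._obs(reference_params)
        fitter = SteadyStateFitter(max_steps=200, random_state=3)
        fitter.fit(obs)
        assert fitter.cost_ < 1e-8
        freqs, amps = obs.arrays()
        assert np.allclose(fitter.predict(freqs), amps, rtol=1e-3)

    def test_cost_trajectory_is_non_increasing(self, reference_params):
        fitter = SteadyStateFitter(max_steps=100, random_state=5)
        fitter.fit(self._obs(reference_params))
        assert np.all(np.diff(fitter.cost_trajectory_) <= 0.0)

    def test_profiled_amplitude_matches_closed_form(self, reference_params):
        freqs = np.array(STANDARD_FREQUENCIES)
        amps = steady_state_curve(reference_params, freqs) * 3.7
        fitter = SteadyStateFitter(frozen=("f", "U", "F", "D"))
        fitter.fit(SteadyStateObservations.from_arrays(freqs, amps),
                   init=reference_params)
        shape = steady_state_curve(reference_params.replace(A=1.0), freqs)
        assert fitter.params_.A == pytest.approx(
            profile_amplitude(shape, amps), rel=1e-10
        )
        assert fitter.params_.A == pytest.approx(3.7, rel=1e-10)

    def test_underdetermined_fit_requires_opt_in(self, reference_params):
        obs = self._obs(reference_params, freqs=[10.0, 20.0, 130.0])
        with pytest.raises(ValueError, match="under"):
            SteadyStateFitter().fit(obs)
        with pytest.warns(UserWarning, match="under-determined"):
            SteadyStateFitter(allow_underdetermined=True, random_state=0).fit(obs)

    def test_three_frequencies_admit_distinct_perfect_fits(self, mixed_params):
        # the steady-state system is under-determined below four frequencies
        obs = self._obs(mixed_params, freqs=[10.0, 20.0, 130.0])
        fits = []
        for seed in range(6):
            f = SteadyStateFitter(
                max_steps=200, allow_underdetermined=True, random_state=seed
            )
            with pytest.warns(UserWarning):
                f.fit(obs)
            if f.cost_ < 1e-10:
                fits.append(f.params_)
        assert len(fits) >= 2
        dists = [
            parameter_distance(a, b)
            for i, a in enumerate(fits)
            for b in fits[i + 1:]
        ]
        assert max(dists) > 0.05

    def test_out_of_bounds_init_is_projected_with_warning(self, reference_params):
        obs = self._obs(reference_params)
        bad = reference_params.replace(F=4.9)
        fitter = SteadyStateFitter(
            bounds={"f": (1e-4, 1), "U": (1e-4, 1), "F": (1e-3, 2), "D": (1e-3, 2)}
        )
        with pytest.warns(UserWarning, match="projected"):
            fitter.fit(obs, init=bad)
        assert fitter.params_.F <= 2.0
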