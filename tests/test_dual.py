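"""Tests of the dual optimizer, its frozen-U variant and the LMSE baseline."""

import numpy as np
import pytest

from stpfit import (
    ConventionalLMSE,
    DualOptimizer,
    MultiFrequencyDataset,
    TMParameters,
    conventional_lmse,
    dual_optimize,
    dual_optimize_frozen_U,
    generate_dataset,
    sample_parameters,
    steady_state_curve,
)
from stpfit.dual import DualOptConfig, random_initial_parameters
from stpfit.model import peak_values

pytestmark = pytest.mark.filterwarnings(
    "ignore:series length.*transient length:UserWarning"
)


class TestDualOptimizer:
    def test_truth_init_on_noiseless_data_returns_truth(
        self, mixed_params, noiseless_dataset
    ):
        est = DualOptimizer(n_outer=1, seed=0)
        est.fit(noiseless_dataset, init=mixed_params)
        assert np.allclose(
            est.params_.as_vector(), mixed_params.as_vector(), atol=1e-6
        )
        # the steady-state observations are last-10-peak means, so the
        # combined cost at truth is only numerically zero
        assert est.combined_cost_ == pytest.approx(0.0, abs=1e-12)

    def test_recovers_reference_parameters_from_random_init(
        self, reference_params, rng
    ):
        data = generate_dataset(
            reference_params, n_pulses=100, noise_sd_frac=0.0, seed=0
        )
        est = DualOptimizer(seed=500)
        est.fit(data, init=random_initial_parameters(rng))
        rel = np.abs(
            est.params_.as_vector() - reference_params.as_vector()
        ) / np.abs(reference_params.as_vector())
        assert np.max(rel) < 0.05

    def test_best_so_far_combined_cost_non_increasing(self, mixed_params):
        data = generate_dataset(mixed_params, n_pulses=100, noise_sd_frac=0.05, seed=2)
        est = DualOptimizer(n_outer=4, seed=3)
        est.fit(data, init=random_initial_parameters(np.random.default_rng(3)))
        costs = [rec[2] for rec in est.history_]
        assert np.all(np.diff(np.minimum.accumulate(costs)) <= 0)
        assert est.combined_cost_ == pytest.approx(min(costs))

    def test_reconstructed_steady_state_curve_matches_observations(
        self, mixed_params, noiseless_dataset
    ):
        est = DualOptimizer(seed=4)
        est.fit(
            noiseless_dataset,
            init=random_initial_parameters(np.random.default_rng(4)),
        )
        freqs, amps = est.observations_.arrays()
        model = steady_state_curve(est.params_, freqs)
        assert np.all(np.abs(model - amps) / np.abs(amps) < 0.01)

    def test_identical_seed_and_data_give_identical_history(self, mixed_params):
        data = generate_dataset(mixed_params, n_pulses=100, noise_sd_frac=0.2, seed=9)
        runs = []
        for _ in range(2):
            est = DualOptimizer(n_outer=3, seed=77)
            est.fit(data)
            runs.append(est.history_)
        assert len(runs[0]) == len(runs[1])
        for a, b in zip(*runs):
            assert a[0] == b[0] and a[1] == b[1]
            assert a[2] == b[2]
            assert np.array_equal(a[3], b[3])

    def test_three_frequencies_require_frozen_u_mode(self, mixed_params):
        data = generate_dataset(
            mixed_params, (10.0, 20.0, 130.0), n_pulses=100, seed=0
        )
        with pytest.raises(ValueError, match="frozen"):
            DualOptimizer(seed=0).fit(data)


class TestFrozenUVariant:
    def test_truth_init_returns_truth(self, mixed_params):
        data = generate_dataset(
            mixed_params, (10.0, 20.0, 130.0), n_pulses=100, seed=0
        )
        result = dual_optimize_frozen_U(
            data, DualOptConfig(n_outer=1, seed=0), init=mixed_params
        )
        assert np.allclose(
            result.params.as_vector(), mixed_params.as_vector(), atol=1e-6
        )

    def test_noiseless_three_frequency_reconstruction(self, mixed_params, rng):
        data = generate_dataset(
            mixed_params, (10.0, 20.0, 130.0), n_pulses=100, seed=1
        )
        est = DualOptimizer(frozen_U=True, seed=21)
        est.fit(data, init=random_initial_parameters(rng))
        max_amp = data.max_amplitude()
        for series in data.series:
            model = peak_values(est.params_, series.frequency, len(series))
            rms = np.sqrt(np.mean((model - series.peaks) ** 2))
            assert rms < 0.02 * max_amp

    def test_halves_step_caps_and_doubles_rounds(self):
        est = DualOptimizer(
            n_outer=4, max_steps_steady=40, max_steps_transient=80, frozen_U=True
        )
        cfg = est._config()
        assert cfg.n_outer == 8
        assert cfg.max_steps_steady == 20
        assert cfg.max_steps_transient == 40
        assert "U" in cfg.frozen


class TestConventionalLMSE:
    def test_truth_init_on_noiseless_data_stays(self, mixed_params, noiseless_dataset):
        result = conventional_lmse(noiseless_dataset, init=mixed_params, max_steps=50)
        assert np.allclose(
            result.params.as_vector(), mixed_params.as_vector(), atol=1e-9
        )

    def test_empty_dataset_rejected(self, mixed_params):
        with pytest.raises(ValueError, match="no peaks"):
            ConventionalLMSE().fit(MultiFrequencyDataset(series=[]))

    def test_cost_trajectory_non_increasing(self, mixed_params):
        data = generate_dataset(mixed_params, n_pulses=60, noise_sd_frac=0.1, seed=5)
        est = ConventionalLMSE(max_steps=100, seed=5)
        est.fit(data, init=random_initial_parameters(np.random.default_rng(5)))
        assert np.all(np.diff(est.cost_trajectory_) <= 0.0)


class TestSensitivityDissociation:
    """Steady state responds to D; the early transient responds to F."""

    def test_depression_constant_moves_steady_state(self):
        blue = TMParameters(f=0.1, U=0.0, F=2.0, D=0.05)
        purple = blue.replace(D=0.5)
        i_blue = steady_state_curve(blue, [50.0])[0]
        i_purple = steady_state_curve(purple, [50.0])[0]
        rel_steady = abs(i_purple - i_blue) / i_blue
        early_blue = peak_values(blue, 50.0, 5)
        early_purple = peak_values(purple, 50.0, 5)
        rel_early = np.sqrt(np.mean((early_purple - early_blue) ** 2)) / np.sqrt(
            np.mean(early_blue**2)
        )
        assert rel_steady > 0.10
        assert rel_early < rel_steady

    def test_facilitation_constant_spares_steady_state(self):
        blue = TMParameters(f=0.1, U=0.0, F=2.0, D=0.05)
        red = blue.replace(F=1.0)
        i_blue = steady_state_curve(blue, [50.0])[0]
        i_red = steady_state_curve(red, [50.0])[0]
        assert abs(i_red - i_blue) / i_blue < 0.05
        early_blue = peak_values(blue, 50.0, 5)
        early_red = peak_values(red, 50.0, 5)
        rel_early = np.sqrt(np.mean((early_red - early_blue) ** 2)) / np.sqrt(
            np.mean(early_blue**2)
        )
        assert rel_early > 0.005
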