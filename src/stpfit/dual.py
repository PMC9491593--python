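"""Dual optimization: alternating steady-state and transient fitting.

Estimating {f, U, F, D} from the steady-state amplitudes alone is a local,
non-unique problem (many parameter sets reproduce the same steady-state
curve but different transients), while the full-length mean-squared-error
fit over-weights the long steady segment and under-constrains the
facilitation time constant.  The dual algorithm alternates the two views:
a bounded trust-region fit to the steady-state curve warm-starts a
Nelder-Mead fit to the transient peaks (with a penalty anchoring the
search near the steady-state estimate), whose output warm-starts the next
steady-state fit, and so on.  With fewer distinct stimulation frequencies
than free parameters the steady-state stage is under-determined; the
frozen-U variant holds the baseline release probability U fixed during
that stage (U moves the steady-state curve least), using smaller per-stage
step caps and more alternation rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable

import numpy as np
from scipy.optimize import minimize

from .datatypes import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    FitResult,
    MultiFrequencyDataset,
    SteadyStateObservations,
    TMParameters,
)
from .model import peak_values
from .steady_state import SteadyStateFitter, steady_state_cost
from .transient import (
    TransientConfig,
    TransientFitter,
    _from_search,
    _initial_simplex,
    _to_search,
    transient_cost,
)

__all__ = [
    "DualOptConfig",
    "DualOptimizer",
    "ConventionalLMSE",
    "dual_optimize",
    "dual_optimize_frozen_U",
    "conventional_lmse",
    "random_initial_parameters",
    "full_series_mse",
]

logger = logging.getLogger(__name__)


@dataclass
class DualOptConfig:
    """Hyper-parameters of the dual optimization loop.

    ``n_outer`` alternation rounds, per-stage step caps, anchor penalty
    weight lambda, optionally frozen steady-state parameters, fitting
    bounds, RNG seed and the relative combined-cost stopping tolerance.
    """

    n_outer: int = 10
    max_steps_steady: int = 50
    max_steps_transient: int = 300
    penalty_factor: float = 0.1
    frozen: frozenset[str] = frozenset()
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int | None = None
    tol: float = 1e-10
    steady_k: int = 10
    change_threshold: float = 0.05
    n_trans_cap: int = 20

    def __post_init__(self) -> None:
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        self.frozen = frozenset(self.frozen)

    def snapshot(self) -> dict:
        return {
            "n_outer": self.n_outer,
            "max_steps_steady": self.max_steps_steady,
            "max_steps_transient": self.max_steps_transient,
            "penalty_factor": self.penalty_factor,
            "frozen": sorted(self.frozen),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "tol": self.tol,
            "steady_k": self.steady_k,
            "change_threshold": self.change_threshold,
            "n_trans_cap": self.n_trans_cap,
        }


def random_initial_parameters(
    rng: np.random.Generator,
    tau_syn: float = 0.003,
    A: float = 1.0,
) -> TMParameters:
    """Random starting point: f, U uniform on [0.05, 0.95]; F, D log-uniform
    on [0.01, 2] s (time constants span decades)."""
    return TMParameters(
        f=float(rng.uniform(0.05, 0.95)),
        U=float(rng.uniform(0.05, 0.95)),
        F=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0)))),
        D=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0)))),
        A=A,
        tau_syn=tau_syn,
    )


def extract_steady_state_observations(
    data: MultiFrequencyDataset, k: int = 10
) -> SteadyStateObservations:
    """Per-frequency steady-state amplitude: mean of the last k peaks."""
    from .traces import steady_state_from_peaks

    return SteadyStateObservations.from_arrays(
        [s.frequency for s in data.series],
        [steady_state_from_peaks(s, k=min(k, len(s))) for s in data.series],
    )


def full_series_mse(params: TMParameters, data: MultiFrequencyDataset) -> float:
    """Mean squared error over the full length of every series, summed over
    frequencies (the conventional-LMSE objective)."""
    total = 0.0
    for series in data.series:
        model = peak_values(params, series.frequency, len(series))
        total += float(np.mean((series.peaks - model) ** 2))
    return total


class DualOptimizer:
    """Alternating steady-state / transient estimator of TM parameters.

    After :meth:`fit`, ``params_`` holds the best parameters over the whole
    optimization history (by combined steady-state + transient cost),
    ``result_`` the full :class:`FitResult` with per-stage cost records.

    ``frozen_U`` switches to the under-determined variant: U is frozen
    during the steady-state stage only, per-stage step caps are halved and
    the number of alternation rounds is doubled.
    """

    def __init__(
        self,
        n_outer: int = 10,
        max_steps_steady: int = 50,
        max_steps_transient: int = 300,
        penalty_factor: float = 0.1,
        frozen: Iterable[str] = (),
        bounds: dict[str, tuple[float, float]] | None = None,
        seed: int | None = None,
        tol: float = 1e-10,
        steady_k: int = 10,
        change_threshold: float = 0.05,
        n_trans_cap: int = 20,
        frozen_U: bool = False,
        profile_A: bool = True,
    ) -> None:
        self.n_outer = n_outer
        self.max_steps_steady = max_steps_steady
        self.max_steps_transient = max_steps_transient
        self.penalty_factor = penalty_factor
        self.frozen = frozen
        self.bounds = bounds
        self.seed = seed
        self.tol = tol
        self.steady_k = steady_k
        self.change_threshold = change_threshold
        self.n_trans_cap = n_trans_cap
        self.frozen_U = frozen_U
        self.profile_A = profile_A

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_outer": self.n_outer,
            "max_steps_steady": self.max_steps_steady,
            "max_steps_transient": self.max_steps_transient,
            "penalty_factor": self.penalty_factor,
            "frozen": self.frozen,
            "bounds": self.bounds,
            "seed": self.seed,
            "tol": self.tol,
            "steady_k": self.steady_k,
            "change_threshold": self.change_threshold,
            "n_trans_cap": self.n_trans_cap,
            "frozen_U": self.frozen_U,
            "profile_A": self.profile_A,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> DualOptConfig:
        cfg = DualOptConfig(
            n_outer=self.n_outer,
            max_steps_steady=self.max_steps_steady,
            max_steps_transient=self.max_steps_transient,
            penalty_factor=self.penalty_factor,
            frozen=frozenset(self.frozen),
            bounds=dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds),
            seed=self.seed,
            tol=self.tol,
            steady_k=self.steady_k,
            change_threshold=self.change_threshold,
            n_trans_cap=self.n_trans_cap,
        )
        if self.frozen_U:
            cfg = dc_replace(
                cfg,
                frozen=cfg.frozen | {"U"},
                n_outer=2 * cfg.n_outer,
                max_steps_steady=max(1, cfg.max_steps_steady // 2),
                max_steps_transient=max(1, cfg.max_steps_transient // 2),
            )
        return cfg

    def fit(
        self, data: MultiFrequencyDataset, init: TMParameters | None = None
    ) -> "DualOptimizer":
        cfg = self._config()
        n_free = len([n for n in PARAM_NAMES if n not in cfg.frozen])
        if data.n_frequencies < n_free:
            raise ValueError(
                f"{data.n_frequencies} frequencies cannot determine {n_free} "
                "free steady-state parameters; use the frozen-U mode "
                "(frozen_U=True / dual_optimize_frozen_U)"
            )
        rng = np.random.default_rng(cfg.seed)
        if init is None:
            init = random_initial_parameters(rng)
        obs = extract_steady_state_observations(data, k=cfg.steady_k)
        plain_cfg = TransientConfig(
            change_threshold=cfg.change_threshold,
            n_trans_cap=cfg.n_trans_cap,
            penalty_factor=0.0,
            bounds=cfg.bounds,
        )

        def combined_cost(p: TMParameters) -> float:
            return steady_state_cost(p, obs) + transient_cost(p, data, plain_cfg)

        history: list[tuple[str, int, float, np.ndarray]] = []
        transient_trajectories: list[list[np.ndarray]] = []
        current = init
        best_params = init
        best_cost = combined_cost(init)
        history.append(("init", 0, best_cost, init.as_vector()))
        prev_round_cost = best_cost

        for round_idx in range(1, cfg.n_outer + 1):
            ss = SteadyStateFitter(
                frozen=cfg.frozen,
                bounds=cfg.bounds,
                max_steps=cfg.max_steps_steady,
                tau_syn=init.tau_syn,
                profile_A=self.profile_A,
                allow_underdetermined=bool(cfg.frozen),
            )
            ss.fit(obs, init=current)
            anchor = ss.params_
            c = combined_cost(anchor)
            history.append(("steady", round_idx, c, anchor.as_vector()))
            if c < best_cost:
                best_cost, best_params = c, anchor

            tr = TransientFitter(
                change_threshold=cfg.change_threshold,
                n_trans_cap=cfg.n_trans_cap,
                penalty_factor=cfg.penalty_factor,
                anchor=anchor,
                bounds=cfg.bounds,
                max_steps=cfg.max_steps_transient,
                profile_A=self.profile_A,
                random_state=int(rng.integers(2**31)),
            )
            tr.fit(data, init=anchor)
            transient_trajectories.append(
                [row.copy() for row in tr.parameter_trajectory_]
            )
            current = tr.params_
            c = combined_cost(current)
            history.append(("transient", round_idx, c, current.as_vector()))
            if c < best_cost:
                best_cost, best_params = c, current

            rel_change = abs(prev_round_cost - c) / max(abs(prev_round_cost), 1e-300)
            if rel_change < cfg.tol:
                logger.debug(
                    "dual optimization stopped at round %d (relative combined-"
                    "cost change %.3g < tol)", round_idx, rel_change,
                )
                break
            prev_round_cost = c

        self.params_ = best_params
        self.combined_cost_ = best_cost
        self.history_ = history
        # per-round transient-stage best-so-far parameter vectors, for
        # iteration-resolved comparisons against the full-length baseline
        self.transient_parameter_trajectories_ = transient_trajectories
        self.observations_ = obs
        self.result_ = FitResult(
            params=best_params,
            stage_history=history,
            total_cost=best_cost,
            config=cfg.snapshot(),
        )
        return self

    def predict(self, frequency: float, n_pulses: int) -> np.ndarray:
        """Peak series generated by the fitted parameters."""
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before calling predict")
        return peak_values(self.params_, frequency, n_pulses)


class ConventionalLMSE:
    """Baseline: Nelder-Mead on the full-length mean squared error.

    No transient truncation and no anchor penalty; the linear scale A is
    profiled analytically at each evaluation.
    """

    def __init__(
        self,
        bounds: dict[str, tuple[float, float]] | None = None,
        max_steps: int = 300,
        seed: int | None = None,
        record_parameters: bool = True,
        profile_A: bool = True,
    ) -> None:
        self.bounds = bounds
        self.max_steps = max_steps
        self.seed = seed
        self.record_parameters = record_parameters
        self.profile_A = profile_A

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bounds": self.bounds,
            "max_steps": self.max_steps,
            "seed": self.seed,
            "record_parameters": self.record_parameters,
            "profile_A": self.profile_A,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self, data: MultiFrequencyDataset, init: TMParameters | None = None
    ) -> "ConventionalLMSE":
        if not data.series or all(len(s) == 0 for s in data.series):
            raise ValueError("dataset contains no peaks to fit")
        bounds = dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds)
        rng = np.random.default_rng(self.seed)
        if init is None:
            init = random_initial_parameters(rng)
        lo = np.array([bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([bounds[n][1] for n in PARAM_NAMES])
        x0 = np.clip(init.as_vector(), lo, hi)
        tau = init.tau_syn
        A0 = init.A
        lo_s, hi_s = _to_search(lo), _to_search(hi)
        best: dict = {"cost": np.inf, "x": x0.copy(), "A": init.A}
        trajectory: list[float] = []
        param_traj: list[np.ndarray] = []

        def objective(s: np.ndarray) -> float:
            if np.any(s < lo_s) or np.any(s > hi_s) or not np.all(np.isfinite(s)):
                return 1e100
            x = _from_search(s)
            p = TMParameters.from_vector(x, A=1.0, tau_syn=tau)
            models = [
                peak_values(p, s.frequency, len(s)) for s in data.series
            ]
            if self.profile_A:
                mm = sum(float(np.dot(m, m)) for m in models)
                my = sum(
                    float(np.dot(m, s.peaks))
                    for m, s in zip(models, data.series)
                )
                A = max(my / mm, 1e-12) if mm > 0 else 1e-12
            else:
                A = A0
            cost = sum(
                float(np.mean((s.peaks - A * m) ** 2))
                for m, s in zip(models, data.series)
            )
            if cost < best["cost"]:
                best["cost"], best["x"], best["A"] = cost, x.copy(), A
            return cost

        def on_iteration(xk: np.ndarray) -> None:
            trajectory.append(best["cost"])
            if self.record_parameters:
                param_traj.append(best["x"].copy())

        s0 = _to_search(x0)
        minimize(
            objective,
            s0,
            method="Nelder-Mead",
            options={
                "maxiter": self.max_steps,
                "xatol": 1e-12,
                "fatol": 1e-14,
                "adaptive": False,
                "initial_simplex": _initial_simplex(s0, lo_s, hi_s),
            },
            callback=on_iteration,
        )
        self.params_ = TMParameters.from_vector(
            best["x"], A=best["A"], tau_syn=tau
        )
        self.cost_ = float(best["cost"])
        self.cost_trajectory_ = (
            np.minimum.accumulate(np.asarray(trajectory))
            if trajectory else np.array([best["cost"]])
        )
        self.parameter_trajectory_ = param_traj
        self.result_ = FitResult(
            params=self.params_,
            stage_history=[
                ("lmse", i + 1, c, (param_traj[i] if param_traj else best["x"]))
                for i, c in enumerate(self.cost_trajectory_)
            ],
            total_cost=self.cost_,
            config={"max_steps": self.max_steps, "seed": self.seed},
        )
        return self

    def predict(self, frequency: float, n_pulses: int) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before calling predict")
        return peak_values(self.params_, frequency, n_pulses)


# -- functional wrappers --------------------------------------------------

def _estimator_from_config(cfg: DualOptConfig, frozen_U: bool) -> DualOptimizer:
    return DualOptimizer(
        n_outer=cfg.n_outer,
        max_steps_steady=cfg.max_steps_steady,
        max_steps_transient=cfg.max_steps_transient,
        penalty_factor=cfg.penalty_factor,
        frozen=cfg.frozen - ({"U"} if frozen_U else set()),
        bounds=cfg.bounds,
        seed=cfg.seed,
        tol=cfg.tol,
        steady_k=cfg.steady_k,
        change_threshold=cfg.change_threshold,
        n_trans_cap=cfg.n_trans_cap,
        frozen_U=frozen_U,
    )


def dual_optimize(
    data: MultiFrequencyDataset,
    cfg: DualOptConfig | None = None,
    init: TMParameters | None = None,
) -> FitResult:
    """Run the dual optimization and return its :class:`FitResult`."""
    est = _estimator_from_config(cfg or DualOptConfig(), frozen_U=False)
    est.fit(data, init=init)
    return est.result_


def dual_optimize_frozen_U(
    data: MultiFrequencyDataset,
    cfg: DualOptConfig | None = None,
    init: TMParameters | None = None,
) -> FitResult:
    """Dual optimization with U frozen during the steady-state stage.

    Relative to the supplied configuration the per-stage step caps are
    halved and the number of alternation rounds doubled.
    """
    est = _estimator_from_config(cfg or DualOptConfig(), frozen_U=True)
    est.fit(data, init=init)
    return est.result_


def conventional_lmse(
    data: MultiFrequencyDataset,
    init: TMParameters | None = None,
    max_steps: int = 300,
    seed: int | None = None,
) -> FitResult:
    """Full-length LMSE baseline fit; returns its :class:`FitResult`."""
    est = ConventionalLMSE(max_steps=max_steps, seed=seed)
    est.fit(data, init=init)
    return est.result_
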