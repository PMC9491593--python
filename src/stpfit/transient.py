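"""Transient-segment detection and derivative-free fitting of the TM model.

The transient part of a peak series is the initial stretch over which
consecutive peaks still change by more than a relative threshold (5% by
default): N_trans is the least n such that |I[m] - I[m-1]| <
threshold * |I[m-1]| for every m >= n.  The transient cost is the
per-frequency mean squared error over the first N_trans peaks, summed over
frequencies, optionally plus a penalty on the normalized distance from an
anchor parameter set (the steady-state stage's estimate in the dual
algorithm).  Because the model recursion has no convenient derivative, the
cost is minimized with the Nelder-Mead simplex method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import minimize

from .datatypes import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    MultiFrequencyDataset,
    PeakSeries,
    TMParameters,
)
from .model import peak_values

__all__ = [
    "TransientConfig",
    "detect_transient_length",
    "transient_cost",
    "TransientFitter",
    "fit_transient",
]

logger = logging.getLogger(__name__)

#: Penalty on out-of-bounds simplex proposals (bound handling by rejection).
_REJECT_COST = 1e100


def _to_search(x: np.ndarray) -> np.ndarray:
    """Raw [f, U, F, D] -> simplex search space [f, U, log F, log D]."""
    s = np.array(x, dtype=float)
    s[2:] = np.log(s[2:])
    return s


def _from_search(s: np.ndarray) -> np.ndarray:
    x = np.array(s, dtype=float)
    x[2:] = np.exp(x[2:])
    return x


def _initial_simplex(s0: np.ndarray, lo_s: np.ndarray, hi_s: np.ndarray) -> np.ndarray:
    """Initial simplex with steps scaled to the search-space bound ranges
    (5% of each range), directed inward at the bounds."""
    steps = 0.05 * (hi_s - lo_s)
    simplex = np.tile(s0, (s0.size + 1, 1))
    for i in range(s0.size):
        step = steps[i] if s0[i] + steps[i] <= hi_s[i] else -steps[i]
        simplex[i + 1, i] = np.clip(s0[i] + step, lo_s[i], hi_s[i])
    return simplex


@dataclass
class TransientConfig:
    """Configuration of transient detection and cost.

    ``change_threshold`` is the relative per-pulse change below which the
    series counts as settled; ``n_trans_default`` is the rule-of-thumb
    transient length used when detection is unavailable; ``n_trans_cap``
    caps the detected length inside fitting; ``penalty_factor`` (lambda)
    scales the squared normalized distance from ``anchor``.
    """

    change_threshold: float = 0.05
    n_trans_default: int = 15
    n_trans_cap: int = 20
    penalty_factor: float = 0.0
    anchor: TMParameters | None = None
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.change_threshold < 1.0:
            raise ValueError("change_threshold must be in (0, 1)")
        if not 1 <= self.n_trans_default <= self.n_trans_cap:
            raise ValueError("require 1 <= n_trans_default <= n_trans_cap")
        if self.penalty_factor < 0:
            raise ValueError("penalty_factor must be nonnegative")


def detect_transient_length(
    peaks: PeakSeries | np.ndarray, threshold: float = 0.05
) -> int:
    """Least n after which all consecutive relative changes stay below
    ``threshold``.

    Absolute changes are used, |I[m] - I[m-1]| < threshold * |I[m-1]|, so
    the criterion is meaningful for depressing (decreasing) series too.  A
    zero previous peak makes that comparison fail (conservative).  Returns
    the series length when the series never settles; never less than 2
    because the criterion compares consecutive pairs.
    """
    values = peaks.peaks if isinstance(peaks, PeakSeries) else np.asarray(peaks)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 peaks to detect a transient")
    prev = values[:-1]
    diff = np.abs(np.diff(values))
    with np.errstate(invalid="ignore"):
        settled = diff < threshold * np.abs(prev)
    zero_prev = prev == 0.0
    if np.any(zero_prev):
        logger.info(
            "zero peak amplitude encountered; treating its relative-change "
            "comparison as unsettled"
        )
        settled = settled & ~zero_prev
    failing = np.nonzero(~settled)[0]  # index m-2 for pair (m-1, m), m>=2
    if failing.size == 0:
        return 2
    last_fail_pulse = int(failing[-1]) + 2  # 1-based pulse index m
    return min(last_fail_pulse + 1, n)


def _series_n_trans(series: PeakSeries, cfg: TransientConfig) -> int:
    if len(series) < 2:
        # detection unavailable: fall back to the rule-of-thumb length
        return cfg.n_trans_default
    return min(detect_transient_length(series, cfg.change_threshold), cfg.n_trans_cap)


def _penalty(params: TMParameters, cfg: TransientConfig) -> float:
    if cfg.penalty_factor == 0.0 or cfg.anchor is None:
        return 0.0
    ranges = np.array(
        [cfg.bounds[n][1] - cfg.bounds[n][0] for n in PARAM_NAMES]
    )
    delta = (params.as_vector() - cfg.anchor.as_vector()) / ranges
    return float(cfg.penalty_factor * np.dot(delta, delta))


def transient_cost(
    params: TMParameters,
    data: MultiFrequencyDataset,
    cfg: TransientConfig | None = None,
) -> float:
    """Summed per-frequency MSE over the transient peaks, plus anchor penalty.

    N_trans is detected per frequency on the observed (reference) data and
    capped at ``cfg.n_trans_cap``; the model prediction comes from the
    discrete TM map.
    """
    cfg = cfg or TransientConfig()
    total = 0.0
    for series in data.series:
        n_trans = _series_n_trans(series, cfg)
        if len(series) < n_trans:
            raise ValueError(
                f"series at {series.frequency} Hz has {len(series)} peaks, "
                f"fewer than the transient length {n_trans}"
            )
        model = peak_values(params, series.frequency, n_trans)
        resid = series.peaks[:n_trans] - model
        total += float(np.mean(resid**2))
    return total + _penalty(params, cfg)


class TransientFitter:
    """Nelder-Mead minimization of the transient cost.

    The simplex moves in the transformed space [f, U, log F, log D] (the
    time constants span decades) with initial steps scaled to the bound
    ranges; out-of-bounds proposals are rejected via a large cost.  The
    best-so-far parameters over all evaluations are returned; on premature
    simplex convergence one restart is made around the best point with 5%
    jitter.  When ``profile_A`` is set, the linear scale A is profiled
    analytically at every evaluation (the kinetic parameters {f, U, F, D}
    are the search space).

    The anchor penalty keeps the search near the steady-state stage's
    estimate without dominating: its weight is expressed relative to the
    transient data cost at the anchor (effective absolute weight =
    ``penalty_factor`` times that cost), so the leash loosens as the
    alternating algorithm converges and the penalty introduces no bias at
    the fixed point.  Set ``penalty_scale="absolute"`` to use
    ``penalty_factor`` directly as lambda.
    """

    def __init__(
        self,
        change_threshold: float = 0.05,
        n_trans_cap: int = 20,
        penalty_factor: float = 0.0,
        anchor: TMParameters | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        max_steps: int = 100,
        profile_A: bool = True,
        penalty_scale: str = "relative",
        restart_jitter: float = 0.05,
        random_state: int | None = None,
    ) -> None:
        self.change_threshold = change_threshold
        self.n_trans_cap = n_trans_cap
        self.penalty_factor = penalty_factor
        self.anchor = anchor
        self.bounds = bounds
        self.max_steps = max_steps
        self.profile_A = profile_A
        self.penalty_scale = penalty_scale
        self.restart_jitter = restart_jitter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "change_threshold": self.change_threshold,
            "n_trans_cap": self.n_trans_cap,
            "penalty_factor": self.penalty_factor,
            "anchor": self.anchor,
            "bounds": self.bounds,
            "max_steps": self.max_steps,
            "profile_A": self.profile_A,
            "penalty_scale": self.penalty_scale,
            "restart_jitter": self.restart_jitter,
            "random_state": self.random_state,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # ------------------------------------------------------------------
    def fit(
        self, data: MultiFrequencyDataset, init: TMParameters
    ) -> "TransientFitter":
        if self.penalty_scale not in ("relative", "absolute"):
            raise ValueError("penalty_scale must be 'relative' or 'absolute'")
        bounds = dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds)
        cfg = TransientConfig(
            change_threshold=self.change_threshold,
            n_trans_cap=self.n_trans_cap,
            penalty_factor=0.0,  # effective lambda is set below
            anchor=self.anchor,
            bounds=bounds,
        )
        lo = np.array([bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([bounds[n][1] for n in PARAM_NAMES])
        x0 = np.clip(init.as_vector(), lo, hi)
        A0, tau = init.A, init.tau_syn

        # transient windows, detected once on the reference data
        windows = [
            (s.frequency, _series_n_trans(s, cfg), s.peaks) for s in data.series
        ]
        for freq, n_trans, peaks in windows:
            if peaks.size < n_trans:
                raise ValueError(
                    f"series at {freq} Hz is shorter than its transient length"
                )

        lo_s, hi_s = _to_search(lo), _to_search(hi)
        best: dict = {"cost": np.inf, "x": x0.copy(), "A": A0}
        trajectory: list[float] = []

        if self.penalty_factor > 0 and self.anchor is not None:
            anchor_cost = transient_cost(self.anchor, data, cfg)
            lam = (
                self.penalty_factor * anchor_cost
                if self.penalty_scale == "relative"
                else self.penalty_factor
            )
            cfg = TransientConfig(
                change_threshold=self.change_threshold,
                n_trans_cap=self.n_trans_cap,
                penalty_factor=lam,
                anchor=self.anchor,
                bounds=bounds,
            )

        def objective(s: np.ndarray) -> float:
            if np.any(s < lo_s) or np.any(s > hi_s) or not np.all(np.isfinite(s)):
                return _REJECT_COST
            x = _from_search(s)
            p = TMParameters.from_vector(x, A=1.0, tau_syn=tau)
            models = [
                peak_values(p, freq, n_trans) for freq, n_trans, _ in windows
            ]
            if self.profile_A:
                mm = sum(float(np.dot(m, m)) for m in models)
                my = sum(
                    float(np.dot(m, peaks[: m.size]))
                    for m, (_, _, peaks) in zip(models, windows)
                )
                A = max(my / mm, 1e-12) if mm > 0 else 1e-12
            else:
                A = A0
            cost = 0.0
            for m, (_, n_trans, peaks) in zip(models, windows):
                resid = peaks[:n_trans] - A * m
                cost += float(np.mean(resid**2))
            cost += _penalty(
                TMParameters.from_vector(x, A=A, tau_syn=tau), cfg
            )
            if cost < best["cost"]:
                best["cost"], best["x"], best["A"] = cost, x.copy(), A
            return cost

        param_traj: list[np.ndarray] = []

        def on_iteration(xk: np.ndarray) -> None:
            trajectory.append(best["cost"])
            param_traj.append(best["x"].copy())

        def run(s_start: np.ndarray, maxiter: int):
            return minimize(
                objective,
                s_start,
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "xatol": 1e-12,
                    "fatol": 1e-14,
                    "adaptive": False,
                    "initial_simplex": _initial_simplex(s_start, lo_s, hi_s),
                },
                callback=on_iteration,
            )

        res = run(_to_search(x0), self.max_steps)
        used = int(res.nit)
        if used < self.max_steps and best["cost"] > 0.0:
            # simplex collapsed early: one jittered restart around the best
            rng = np.random.default_rng(self.random_state)
            s_best = _to_search(best["x"])
            jitter = self.restart_jitter * (hi_s - lo_s) * rng.standard_normal(4)
            s_restart = np.clip(s_best + jitter, lo_s, hi_s)
            run(s_restart, self.max_steps - used)

        self.params_ = TMParameters.from_vector(
            best["x"], A=best["A"], tau_syn=tau
        )
        self.cost_ = float(best["cost"])
        self.cost_trajectory_ = (
            np.minimum.accumulate(np.asarray(trajectory))
            if trajectory else np.array([best["cost"]])
        )
        self.n_iter_ = len(trajectory)
        self.parameter_trajectory_ = param_traj
        self.config_ = cfg
        return self

    def predict(self, frequency: float, n_pulses: int) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before calling predict")
        return peak_values(self.params_, frequency, n_pulses)


def fit_transient(
    data: MultiFrequencyDataset,
    init: TMParameters,
    cfg: TransientConfig | None = None,
    max_steps: int = 100,
    **kwargs,
) -> tuple[TMParameters, np.ndarray]:
    """Functional wrapper: fit and return (parameters, cost trajectory)."""
    cfg = cfg or TransientConfig()
    fitter = TransientFitter(
        change_threshold=cfg.change_threshold,
        n_trans_cap=cfg.n_trans_cap,
        penalty_factor=cfg.penalty_factor,
        anchor=cfg.anchor,
        bounds=cfg.bounds,
        max_steps=max_steps,
        **kwargs,
    )
    fitter.fit(data, init)
    return fitter.params_, fitter.cost_trajectory_
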