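"""Closed-form steady-state response of the TM map and derivative-based fitting.

Under constant-frequency stimulation the per-pulse recursion converges to a
fixed point.  With x = exp(-1/(nu*F)), y = exp(-1/(nu*D)) and
z = exp(-1/(nu*tau_syn)) at stimulation frequency nu,

    u_inf = (f + (1-f)*U*(1-x)) / (1 - (1-f)*x)
    R_inf = (1-y) / (1 - (1-u_inf)*y)
    I_inf = A * u_inf * R_inf / (1-z)

The fitter minimizes the sum of squared residuals between observed and
model steady-state amplitudes across frequencies with a bounded
trust-region least-squares method and an analytic Jacobian.  The scale A is
linear in I_inf and is profiled out analytically, which makes the fit a
function of the kinetic parameters {f, U, F, D} only.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    SteadyStateObservations,
    SteadyStateResponse,
    TMParameters,
)

__all__ = [
    "steady_state_response",
    "steady_state_curve",
    "steady_state_gradient",
    "steady_state_cost",
    "profile_amplitude",
    "SteadyStateFitter",
    "fit_steady_state",
]

logger = logging.getLogger(__name__)


def _fixed_point(
    f: float, U: float, F: float, D: float, tau_syn: float, freq: np.ndarray
):
    x = np.exp(-1.0 / (freq * F))
    y = np.exp(-1.0 / (freq * D))
    z = np.exp(-1.0 / (freq * tau_syn))
    u = (f + (1.0 - f) * U * (1.0 - x)) / (1.0 - (1.0 - f) * x)
    R = (1.0 - y) / (1.0 - (1.0 - u) * y)
    shape = u * R / (1.0 - z)  # I_inf at A = 1
    return u, R, shape


def steady_state_response(
    params: TMParameters, frequency: float
) -> SteadyStateResponse:
    """Steady-state (u_inf, R_inf, I_inf) at one stimulation frequency."""
    if not frequency > 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    u, R, shape = _fixed_point(
        params.f, params.U, params.F, params.D, params.tau_syn,
        np.asarray(frequency, dtype=float),
    )
    return SteadyStateResponse(
        u_inf=float(u), R_inf=float(R), I_inf=float(params.A * shape),
        frequency=float(frequency),
    )


def steady_state_curve(params: TMParameters, frequencies) -> np.ndarray:
    """Vectorized I_inf over an array of frequencies."""
    freq = np.asarray(frequencies, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequencies must be > 0")
    _, _, shape = _fixed_point(
        params.f, params.U, params.F, params.D, params.tau_syn, freq
    )
    return params.A * shape


def steady_state_gradient(params: TMParameters, frequencies) -> np.ndarray:
    """Analytic gradient of I_inf with respect to (f, U, F, D, A).

    Returns an array of shape (n_frequencies, 5).
    """
    freq = np.atleast_1d(np.asarray(frequencies, dtype=float))
    f, U, F, D, A, tau = (
        params.f, params.U, params.F, params.D, params.A, params.tau_syn,
    )
    x = np.exp(-1.0 / (freq * F))
    y = np.exp(-1.0 / (freq * D))
    z = np.exp(-1.0 / (freq * tau))
    N = f + (1.0 - f) * U * (1.0 - x)
    M = 1.0 - (1.0 - f) * x
    u = N / M
    Q = 1.0 - (1.0 - u) * y
    R = (1.0 - y) / Q

    du_df = ((1.0 - U * (1.0 - x)) * M - N * x) / M**2
    du_dU = (1.0 - f) * (1.0 - x) / M
    du_dx = (1.0 - f) * (N - U * M) / M**2
    dx_dF = x / (freq * F**2)
    dR_du = -(1.0 - y) * y / Q**2
    dR_dy = (-Q + (1.0 - y) * (1.0 - u)) / Q**2
    dy_dD = y / (freq * D**2)

    pref = A / (1.0 - z)
    chain_u = pref * (R + u * dR_du)  # dI/du at fixed R-dependence on u folded in
    grad = np.empty((freq.size, 5))
    grad[:, 0] = chain_u * du_df
    grad[:, 1] = chain_u * du_dU
    grad[:, 2] = chain_u * du_dx * dx_dF
    grad[:, 3] = pref * u * dR_dy * dy_dD
    grad[:, 4] = u * R / (1.0 - z)
    return grad


def steady_state_cost(
    params: TMParameters, obs: SteadyStateObservations
) -> float:
    """Sum of squared residuals between observed and model I_inf."""
    if not obs:
        raise ValueError("observations must be nonempty")
    freqs, amps = (
        obs.arrays() if isinstance(obs, SteadyStateObservations)
        else SteadyStateObservations(obs).arrays()
    )
    model = steady_state_curve(params, freqs)
    return float(np.sum((amps - model) ** 2))


def profile_amplitude(shape: np.ndarray, observed: np.ndarray) -> float:
    """Closed-form optimal scale A for model shape s against observations y.

    Minimizes ||y - A*s||^2, giving A = <s, y> / <s, s>, floored at a small
    positive value to respect A > 0.
    """
    ss = float(np.dot(shape, shape))
    if ss == 0.0:
        return 1e-12
    return max(float(np.dot(shape, observed)) / ss, 1e-12)


class SteadyStateFitter:
    """Trust-region least-squares fit of TM parameters to steady-state data.

    Parameters
    ----------
    frozen : iterable of str
        Kinetic parameters held fixed at their initial values (subset of
        {"f", "U", "F", "D"}).
    profile_A : bool
        Profile the linear scale A analytically at each evaluation
        (default) instead of keeping the initial A.
    bounds : mapping
        Per-parameter (low, high) fitting bounds.
    max_steps : int
        Maximum number of trust-region iterations.
    tau_syn : float
        Synaptic decay time constant (seconds) used by the model curve.
    allow_underdetermined : bool
        Permit fewer observations than free parameters (the frozen-U path
        sets this); otherwise such fits raise.
    random_state : int or None
        Seed for the random initial guess when none is supplied to ``fit``.
    """

    def __init__(
        self,
        frozen: Iterable[str] = (),
        profile_A: bool = True,
        bounds: dict[str, tuple[float, float]] | None = None,
        max_steps: int = 50,
        tol: float = 1e-12,
        tau_syn: float = 0.003,
        allow_underdetermined: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.frozen = frozen
        self.profile_A = profile_A
        self.bounds = bounds
        self.max_steps = max_steps
        self.tol = tol
        self.tau_syn = tau_syn
        self.allow_underdetermined = allow_underdetermined
        self.random_state = random_state

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "frozen": self.frozen,
            "profile_A": self.profile_A,
            "bounds": self.bounds,
            "max_steps": self.max_steps,
            "tol": self.tol,
            "tau_syn": self.tau_syn,
            "allow_underdetermined": self.allow_underdetermined,
            "random_state": self.random_state,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _resolved_bounds(self) -> dict[str, tuple[float, float]]:
        return dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds)

    # ---------------------------------------------------------------------
    def fit(
        self,
        X,
        y=None,
        init: TMParameters | None = None,
    ) -> "SteadyStateFitter":
        """Fit to steady-state observations.

        ``X`` may be a :class:`SteadyStateObservations` mapping, or an array
        of frequencies with ``y`` the observed amplitudes.
        """
        if isinstance(X, (SteadyStateObservations, dict)):
            obs = (
                X if isinstance(X, SteadyStateObservations)
                else SteadyStateObservations(X)
            )
            freqs, amps = obs.arrays()
        else:
            freqs = np.asarray(X, dtype=float).ravel()
            amps = np.asarray(y, dtype=float).ravel()
        if freqs.size == 0:
            raise ValueError("observations must be nonempty")

        frozen = set(self.frozen)
        unknown = frozen - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown frozen parameters: {sorted(unknown)}")
        free = [name for name in PARAM_NAMES if name not in frozen]
        if freqs.size < len(free) and not self.allow_underdetermined:
            raise ValueError(
                f"{freqs.size} observations cannot determine {len(free)} free "
                "parameters; freeze parameters or set allow_underdetermined=True"
            )
        if freqs.size < len(free):
            warnings.warn(
                "steady-state fit is under-determined "
                f"({freqs.size} observations, {len(free)} free parameters)",
                stacklevel=2,
            )

        bounds = self._resolved_bounds()
        rng = np.random.default_rng(self.random_state)
        if init is None:
            init = TMParameters(
                f=rng.uniform(0.05, 0.95),
                U=rng.uniform(0.05, 0.95),
                F=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0)))),
                D=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0)))),
                tau_syn=self.tau_syn,
            )
        full = dict(zip(PARAM_NAMES, init.as_vector()))
        lo = np.array([bounds[n][0] for n in free])
        hi = np.array([bounds[n][1] for n in free])
        x0 = np.array([full[n] for n in free])
        clipped = np.clip(x0, lo, hi)
        if np.any(clipped != x0):
            warnings.warn(
                "initial parameters outside bounds were projected onto the "
                "bounds", stacklevel=2,
            )
            x0 = clipped

        A_fixed = init.A
        tau = init.tau_syn
        eval_costs: list[float] = []

        if not free:
            # all kinetic parameters frozen: only the scale A is (optionally)
            # profiled against the observed curve
            p = init
            shape = steady_state_curve(p.replace(A=1.0), freqs)
            if self.profile_A:
                p = p.replace(A=profile_amplitude(shape, amps))
            cost = float(np.sum((amps - steady_state_curve(p, freqs)) ** 2))
            self.params_ = p
            self.cost_ = cost
            self.cost_evaluations_ = np.array([cost])
            self.cost_trajectory_ = np.array([cost])
            self.n_iter_ = 0
            self.frozen_ = frozen
            self.observations_ = SteadyStateObservations.from_arrays(freqs, amps)
            return self

        def build(xfree: np.ndarray) -> TMParameters:
            vals = dict(full)
            vals.update(zip(free, xfree))
            return TMParameters(
                f=vals["f"], U=vals["U"], F=vals["F"], D=vals["D"],
                A=A_fixed, tau_syn=tau,
            )

        def residuals(xfree: np.ndarray) -> np.ndarray:
            p = build(xfree)
            shape = steady_state_curve(p.replace(A=1.0), freqs)
            A = profile_amplitude(shape, amps) if self.profile_A else A_fixed
            r = amps - A * shape
            cost = float(np.sum(r**2))
            if not np.isfinite(cost):
                raise FloatingPointError("non-finite steady-state cost")
            eval_costs.append(cost)
            return r

        def jacobian(xfree: np.ndarray) -> np.ndarray:
            p = build(xfree)
            shape = steady_state_curve(p.replace(A=1.0), freqs)
            grad = steady_state_gradient(p.replace(A=1.0), freqs)  # (n, 5)
            cols = {name: grad[:, i] for i, name in enumerate(PARAM_NAMES)}
            ds = np.column_stack([cols[n] for n in free])  # (n, n_free)
            if self.profile_A:
                ss = float(np.dot(shape, shape))
                A = profile_amplitude(shape, amps)
                dA = (ds.T @ amps - 2.0 * A * (ds.T @ shape)) / ss
                return -A * ds - np.outer(shape, dA)
            return -ds

        result = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=(lo, hi),
            method="trf",
            max_nfev=self.max_steps,
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
        )
        p = build(result.x)
        if self.profile_A:
            shape = steady_state_curve(p.replace(A=1.0), freqs)
            p = p.replace(A=profile_amplitude(shape, amps))
        self.params_ = p
        self.cost_ = float(np.sum(result.fun**2))
        self.cost_evaluations_ = np.asarray(eval_costs)
        self.cost_trajectory_ = np.minimum.accumulate(self.cost_evaluations_)
        self.n_iter_ = int(result.nfev)
        self.frozen_ = frozen
        self.observations_ = SteadyStateObservations.from_arrays(freqs, amps)
        return self

    def predict(self, X) -> np.ndarray:
        """Model steady-state amplitudes at the given frequencies."""
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before calling predict")
        return steady_state_curve(self.params_, np.asarray(X, dtype=float))


def fit_steady_state(
    obs: SteadyStateObservations | dict,
    init: TMParameters | None = None,
    frozen: Iterable[str] = (),
    max_steps: int = 50,
    **kwargs,
) -> tuple[TMParameters, np.ndarray]:
    """Functional wrapper: fit and return (parameters, cost trajectory)."""
    fitter = SteadyStateFitter(frozen=frozen, max_steps=max_steps, **kwargs)
    fitter.fit(obs, init=init)
    return fitter.params_, fitter.cost_trajectory_
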