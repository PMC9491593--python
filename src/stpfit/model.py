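"""Exact simulation of the extended Tsodyks-Markram model.

Between stimulation pulses every state variable relaxes as a pure
exponential (u toward U with time constant F, R toward 1 with D, I toward 0
with tau_syn), so the model is integrated event-driven in closed form; no
numerical ODE solver is involved anywhere.  At each pulse the jump maps are

    u(t+) = f + (1 - f) * u(t-)          (facilitation)
    R(t+) = R(t-) * (1 - u(t+))          (resource depletion)
    I(t+) = I(t-) + A * u(t+) * R(t-)    (PSC peak increment)

Resource depletion uses the post-facilitation utilization u(t+), the
convention under which the discrete per-pulse recursion and the closed-form
steady state are mutually consistent.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datatypes import ContinuousTrace, PeakSeries, StimTrain, TMParameters

__all__ = [
    "simulate_discrete",
    "simulate_continuous",
    "render_trace",
    "discrete_states",
    "peak_values",
]

logger = logging.getLogger(__name__)


def _iterate(
    f: float,
    U: float,
    F: float,
    D: float,
    A: float,
    tau_syn: float,
    frequency: float,
    n_pulses: int,
):
    """Run the per-pulse recursion; returns (u, R, I) float lists.

    u[n] is the post-pulse utilization u(t_n+), R[n] the pre-pulse resource
    fraction R(t_n-), I[n] the post-pulse peak I(t_n+); before the first
    pulse u = U, R = 1, I = 0.
    """
    dt = 1.0 / frequency
    eF = math.exp(-dt / F)
    eD = math.exp(-dt / D)
    eI = math.exp(-dt / tau_syn)
    us: list[float] = []
    Rs: list[float] = []
    Is: list[float] = []
    u_prev = U  # u(t_1-) = U
    R_minus = 1.0
    I_prev = 0.0
    for n in range(n_pulses):
        if n > 0:
            u_minus = U + (u_prev - U) * eF
            R_minus = 1.0 - (1.0 - R_minus * (1.0 - u_prev)) * eD
        else:
            u_minus = U
            R_minus = 1.0
        u_plus = f + (1.0 - f) * u_minus
        I_now = I_prev * eI + A * u_plus * R_minus
        us.append(u_plus)
        Rs.append(R_minus)
        Is.append(I_now)
        u_prev = u_plus
        I_prev = I_now
    return us, Rs, Is


def peak_values(params: TMParameters, frequency: float, n_pulses: int) -> np.ndarray:
    """Per-pulse PSC peaks I[1..n_pulses] at one frequency (fast path)."""
    _, _, Is = _iterate(
        params.f, params.U, params.F, params.D, params.A, params.tau_syn,
        frequency, n_pulses,
    )
    return np.asarray(Is, dtype=float)


def discrete_states(
    params: TMParameters, train: StimTrain
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full state trajectories (u[n], R[n], I[n]) of the per-pulse map."""
    us, Rs, Is = _iterate(
        params.f, params.U, params.F, params.D, params.A, params.tau_syn,
        train.frequency, train.n_pulses,
    )
    return np.asarray(us), np.asarray(Rs), np.asarray(Is)


def simulate_discrete(params: TMParameters, train: StimTrain) -> PeakSeries:
    """Simulate the discrete-time TM map over a constant-frequency train.

    Returns the peak series I[n], n = 1..n_pulses.  An empty train yields an
    empty series.
    """
    return PeakSeries(
        frequency=train.frequency,
        peaks=peak_values(params, train.frequency, train.n_pulses),
    )


def _event_states(params: TMParameters, stim_times: np.ndarray):
    """Exact continuous-time states just after each pulse of an arbitrary
    (not necessarily uniform) sorted pulse-time list.

    Returns (u_plus, R_minus, I_plus) arrays, one entry per pulse.
    """
    f, U, F, D, A, tau = (
        params.f, params.U, params.F, params.D, params.A, params.tau_syn,
    )
    u = U
    R = 1.0
    I = 0.0
    t_prev = None
    u_out, R_out, I_out = [], [], []
    for t in stim_times:
        if t_prev is not None:
            gap = t - t_prev
            u = U + (u - U) * math.exp(-gap / F)
            R = 1.0 - (1.0 - R) * math.exp(-gap / D)
            I = I * math.exp(-gap / tau)
        u_plus = f + (1.0 - f) * u
        R_minus = R
        I = I + A * u_plus * R_minus
        u_out.append(u_plus)
        R_out.append(R_minus)
        I_out.append(I)
        u = u_plus
        R = R_minus * (1.0 - u_plus)
        t_prev = t
    return np.asarray(u_out), np.asarray(R_out), np.asarray(I_out)


def continuous_peak_values(params: TMParameters, stim_times) -> np.ndarray:
    """Post-pulse currents I(t_n+) of the event-driven continuous solution."""
    stim = np.asarray(stim_times, dtype=float)
    _, _, I = _event_states(params, stim)
    return I


def simulate_continuous(
    params: TMParameters,
    stim_times,
    dt: float,
    t_end: float | None = None,
) -> ContinuousTrace:
    """Integrate the continuous three-state TM system exactly.

    The state is propagated analytically between pulses and the jump maps
    applied at each pulse; the current is then sampled onto a uniform grid
    of spacing ``dt``.  Peaks are exact (event-driven) regardless of ``dt``.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    stim = np.asarray(stim_times, dtype=float)
    if stim.size > 1:
        gaps = np.diff(stim)
        if np.any(gaps <= 0):
            raise ValueError("stim_times must be strictly increasing")
        if dt > gaps.min():
            logger.warning(
                "dt=%g exceeds the smallest inter-pulse interval %g; the grid "
                "undersamples the trace but pulse-time peaks remain exact",
                dt, gaps.min(),
            )
    tau = params.tau_syn
    if t_end is None:
        t_end = (stim[-1] + 5.0 * tau) if stim.size else 10.0 * tau
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    current = np.zeros_like(times)
    if stim.size == 0:
        return ContinuousTrace(times=times, current=current, stim_times=stim)

    _, _, I_plus = _event_states(params, stim)
    # between pulse k and k+1 the current is I_plus[k] * exp(-(t - t_k)/tau)
    idx = np.searchsorted(stim, times, side="right") - 1
    inside = idx >= 0
    current[inside] = I_plus[idx[inside]] * np.exp(
        -(times[inside] - stim[idx[inside]]) / tau
    )
    return ContinuousTrace(times=times, current=current, stim_times=stim)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Analytic time-to-peak of the double-exponential kernel."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise)
        * math.log(tau_decay / tau_rise)
    )


def double_exponential_kernel(
    t: np.ndarray, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials PSC kernel.

    ``k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / k_max`` for t >= 0 and
    zero for t < 0, normalized so its maximum equals 1.
    """
    if not (0 < tau_rise < tau_decay):
        raise ValueError("kernel requires 0 < tau_rise < tau_decay")
    t = np.asarray(t, dtype=float)
    t_star = kernel_peak_time(tau_rise, tau_decay)
    norm = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    out = np.where(
        t >= 0.0,
        (np.exp(-np.clip(t, 0.0, None) / tau_decay)
         - np.exp(-np.clip(t, 0.0, None) / tau_rise)) / norm,
        0.0,
    )
    return out


def render_trace(
    peaks: PeakSeries,
    kernel: tuple[float, float],
    dt: float = 1e-4,
    t_end: float | None = None,
) -> ContinuousTrace:
    """Render a peak series into a continuous trace by kernel superposition.

    Each pulse contributes one peak-normalized double-exponential kernel
    scaled by that pulse's amplitude; overlapping kernels add linearly.
    """
    tau_rise, tau_decay = kernel
    if not (0 < tau_rise < tau_decay):
        raise ValueError("degenerate kernel: require 0 < tau_rise < tau_decay")
    stim = np.arange(1, len(peaks) + 1) / peaks.frequency
    if t_end is None:
        t_end = (stim[-1] if stim.size else 0.0) + 8.0 * tau_decay
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    current = np.zeros_like(times)
    for t_pulse, amp in zip(stim, peaks.peaks):
        current += amp * double_exponential_kernel(times - t_pulse, tau_rise, tau_decay)
    return ContinuousTrace(times=times, current=current, stim_times=stim)
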