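"""Bridging raw PSC time traces and per-pulse peak series.

Covers peak extraction at known stimulation times (with a blanking window
for the stimulation artifact), least-squares fitting of the
double-exponential PSC kernel, and steady-state estimation from recorded
peak series.  Compound excitatory/inhibitory responses are not decomposed;
the caller selects the sign of the response of interest (inhibitory
responses appear as the positive peak in the recordings this supports).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datatypes import ContinuousTrace, PeakSeries
from .model import double_exponential_kernel

__all__ = [
    "extract_peaks",
    "fit_kernel",
    "KernelFit",
    "steady_state_from_peaks",
]

logger = logging.getLogger(__name__)


def extract_peaks(
    trace: ContinuousTrace,
    stim_times=None,
    window: float = 0.005,
    sign: int = 1,
    blank: float = 0.001,
) -> PeakSeries:
    """Per-pulse peak amplitudes relative to the pre-pulse baseline.

    For each pulse the extremum of ``sign * current`` over
    ``(t_pulse + blank, t_pulse + window]`` is measured relative to the
    baseline sample just before the pulse.  ``window`` must be shorter than
    the inter-pulse interval so that peak windows do not overlap.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    stim = np.asarray(
        trace.stim_times if stim_times is None else stim_times, dtype=float
    )
    if stim.size == 0:
        return PeakSeries(frequency=np.nan, peaks=np.empty(0))
    if stim.size > 1:
        interval = float(np.min(np.diff(stim)))
        if window >= interval:
            raise ValueError(
                f"window {window}s is not shorter than the inter-pulse "
                f"interval {interval}s; peak windows would overlap"
            )
        frequency = 1.0 / float(np.median(np.diff(stim)))
    else:
        frequency = np.nan
    if stim[0] < trace.times[0] or stim[-1] > trace.times[-1]:
        raise ValueError("trace does not cover all stimulation times")
    if not blank < window:
        raise ValueError("blanking window must be shorter than the search window")

    amps = []
    for t_pulse in stim:
        i_base = int(np.searchsorted(trace.times, t_pulse, side="left")) - 1
        baseline = trace.current[max(i_base, 0)]
        sel = (trace.times > t_pulse + blank) & (trace.times <= t_pulse + window)
        if not np.any(sel):
            raise ValueError(
                f"no samples in the peak window after the pulse at {t_pulse}s"
            )
        seg = sign * (trace.current[sel] - baseline)
        amps.append(float(np.max(seg)))
    return PeakSeries(frequency=frequency, peaks=np.asarray(amps))


@dataclass(frozen=True)
class KernelFit:
    """Result of a double-exponential kernel fit."""

    tau_rise: float
    tau_decay: float
    amplitude: float
    onset: float
    residual: float


def fit_kernel(segment: ContinuousTrace) -> KernelFit:
    """Least-squares fit of an amplitude-scaled, peak-normalized
    double-exponential kernel to a single-response segment.

    The fitted parameters are (tau_rise, tau_decay, amplitude, onset);
    tau_rise < tau_decay is enforced by sorting.  Raises when the segment
    carries no response or the fit fails to converge.
    """
    t = segment.times
    y = segment.current
    peak_abs = float(np.max(np.abs(y))) if y.size else 0.0
    if y.size < 5 or peak_abs == 0.0:
        raise ValueError("segment contains no response to fit")

    i_peak = int(np.argmax(np.abs(y)))
    amp0 = float(y[i_peak])
    t_peak = t[i_peak]
    # crude decay-time initializer: time for |y| to fall to 1/e of the peak
    tail = np.nonzero(np.abs(y[i_peak:]) < abs(amp0) / np.e)[0]
    tau_decay0 = float(t[i_peak + tail[0]] - t_peak) if tail.size else float(
        (t[-1] - t_peak) or 1e-3
    )
    tau_decay0 = max(tau_decay0, 2e-4)
    tau_rise0 = tau_decay0 / 10.0
    onset0 = float(max(t[0], t_peak - 2.0 * tau_rise0 - (t_peak - t[0]) * 0.5))

    def model(x: np.ndarray) -> np.ndarray:
        tr, td, amp, onset = x
        lo_, hi_ = sorted((abs(tr), abs(td)))
        lo_ = max(lo_, 1e-6)
        hi_ = max(hi_, lo_ * (1.0 + 1e-9))
        return amp * double_exponential_kernel(t - onset, lo_, hi_)

    def residuals(x: np.ndarray) -> np.ndarray:
        return model(x) - y

    x0 = np.array([tau_rise0, tau_decay0, amp0, onset0])
    result = least_squares(residuals, x0, method="lm", max_nfev=2000)
    resid = float(np.sqrt(np.mean(result.fun**2)))
    if not result.success or resid > 0.5 * peak_abs:
        raise RuntimeError(
            f"kernel fit did not converge (RMS residual {resid:.3g} against "
            f"peak amplitude {peak_abs:.3g})"
        )
    tr, td = sorted((abs(float(result.x[0])), abs(float(result.x[1]))))
    return KernelFit(
        tau_rise=tr,
        tau_decay=td,
        amplitude=float(result.x[2]),
        onset=float(result.x[3]),
        residual=resid,
    )


def steady_state_from_peaks(peaks: PeakSeries, k: int = 10) -> float:
    """Steady-state amplitude estimate: mean of the last k peaks."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(peaks)
    if n < k:
        raise ValueError(f"series has {n} peaks, fewer than k={k}")
    if n >= 2:
        from .transient import detect_transient_length

        n_trans = detect_transient_length(peaks)
        if n < n_trans + k:
            warnings.warn(
                f"series length {n} is below the detected transient length "
                f"{n_trans} plus k={k}; the steady-state estimate may include "
                "transient pulses",
                stacklevel=2,
            )
    return float(np.mean(peaks.peaks[-k:]))
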