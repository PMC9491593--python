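"""Core data containers for short-term plasticity model fitting.

The extended Tsodyks-Markram (TM) model describes a synapse driven by a
periodic (DBS-like) pulse train through two state variables: the
neurotransmitter utilization probability ``u`` (facilitation) and the
fraction of available resources ``R`` (depression).  The observable is the
per-pulse peak of the postsynaptic current (PSC), ``I[n]``.  The model
parameter vector is ``theta = {f, U, F, D}`` plus the absolute synaptic
efficacy ``A`` and the synaptic decay time constant ``tau_syn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "TMParameters",
    "StimTrain",
    "SimState",
    "PeakSeries",
    "ContinuousTrace",
    "MultiFrequencyDataset",
    "SteadyStateResponse",
    "SteadyStateObservations",
    "FitResult",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
]

#: Names of the four kinetic parameters fitted by the optimizers.
PARAM_NAMES = ("f", "U", "F", "D")

#: Fitting bounds: f, U are probabilities; F, D are time constants in
#: seconds kept within physiological STP ranges so the per-pulse
#: exponentials stay well conditioned.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (1e-4, 1.0),
    "U": (1e-4, 1.0),
    "F": (1e-3, 5.0),
    "D": (1e-3, 5.0),
}


class ParameterError(ValueError):
    """Raised when a model parameter violates its physical bounds."""


@dataclass(frozen=True)
class TMParameters:
    """Parameters of the four-parameter TM model.

    Parameters
    ----------
    f : float
        Magnitude of facilitation (per-pulse increment of utilization),
        dimensionless, in [0, 1].
    U : float
        Baseline release probability toward which ``u`` relaxes,
        dimensionless, in [0, 1].
    F : float
        Facilitation time constant, seconds, > 0.
    D : float
        Depression (resource recovery) time constant, seconds, > 0.
    A : float
        Absolute synaptic efficacy, amplitude units, > 0.
    tau_syn : float
        Synaptic current decay time constant, seconds, > 0.  About 3 ms
        for glutamatergic and 10 ms for GABAergic synapses.
    """

    f: float
    U: float
    F: float
    D: float
    A: float = 1.0
    tau_syn: float = 0.003

    def __post_init__(self) -> None:
        checks = (
            ("f", self.f, 0.0 <= self.f <= 1.0, "0 <= f <= 1"),
            ("U", self.U, 0.0 <= self.U <= 1.0, "0 <= U <= 1"),
            ("F", self.F, self.F > 0.0, "F > 0"),
            ("D", self.D, self.D > 0.0, "D > 0"),
            ("A", self.A, self.A > 0.0, "A > 0"),
            ("tau_syn", self.tau_syn, self.tau_syn > 0.0, "tau_syn > 0"),
        )
        for name, value, ok, bound in checks:
            if not np.isfinite(value) or not ok:
                raise ParameterError(
                    f"parameter {name}={value!r} violates bound {bound}"
                )

    def as_vector(self) -> np.ndarray:
        """Return the kinetic parameter vector [f, U, F, D]."""
        return np.array([self.f, self.U, self.F, self.D], dtype=float)

    def replace(self, **kwargs: float) -> "TMParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_vector(
        cls,
        vector: Sequence[float],
        A: float = 1.0,
        tau_syn: float = 0.003,
    ) -> "TMParameters":
        f, U, F, D = (float(v) for v in vector)
        return cls(f=f, U=U, F=F, D=D, A=A, tau_syn=tau_syn)

    def to_dict(self) -> dict[str, float]:
        return {
            "f": self.f,
            "U": self.U,
            "F": self.F,
            "D": self.D,
            "A": self.A,
            "tau_syn": self.tau_syn,
        }


@dataclass(frozen=True)
class StimTrain:
    """A constant-frequency stimulation pulse train.

    Pulse ``n`` (1-based) occurs at ``t_n = n / frequency`` seconds.
    """

    frequency: float
    n_pulses: int

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.n_pulses < 0:
            raise ValueError(f"n_pulses must be >= 0, got {self.n_pulses}")

    @property
    def interval(self) -> float:
        """Inter-pulse interval 1/frequency in seconds."""
        return 1.0 / self.frequency

    @property
    def pulse_times(self) -> np.ndarray:
        return np.arange(1, self.n_pulses + 1) / self.frequency


@dataclass(frozen=True)
class SimState:
    """Model state at one pulse: post-pulse u, pre-pulse R, post-pulse I."""

    u: float
    R: float
    I: float


@dataclass
class PeakSeries:
    """Ordered per-pulse PSC peak amplitudes at one stimulation frequency."""

    frequency: float
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.peaks.ndim != 1:
            raise ValueError("peaks must be one-dimensional")
        if self.peaks.size and not np.all(np.isfinite(self.peaks)):
            raise ValueError("peaks must be finite")

    def __len__(self) -> int:
        return int(self.peaks.size)


@dataclass
class ContinuousTrace:
    """A uniformly sampled PSC time trace with known stimulation times."""

    times: np.ndarray
    current: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have the same shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MultiFrequencyDataset:
    """Peak series across several stimulation frequencies.

    ``truth`` carries the generating parameters for synthetic data;
    ``noise_sd_frac`` is the additive Gaussian noise standard deviation as
    a fraction of the maximum absolute clean amplitude over the dataset.
    """

    series: list[PeakSeries]
    truth: TMParameters | None = None
    noise_sd_frac: float = 0.0
    seed: int | None = None
    protocol: str = ""

    def __post_init__(self) -> None:
        freqs = [s.frequency for s in self.series]
        if len(set(freqs)) != len(freqs):
            raise ValueError("series frequencies must be distinct")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency for s in self.series], dtype=float)

    @property
    def n_frequencies(self) -> int:
        return len(self.series)

    def get(self, frequency: float) -> PeakSeries:
        for s in self.series:
            if s.frequency == frequency:
                return s
        raise KeyError(f"no series at {frequency} Hz")

    def max_amplitude(self) -> float:
        """Maximum absolute peak over the whole dataset."""
        if not self.series:
            return 0.0
        return max(float(np.max(np.abs(s.peaks))) for s in self.series if len(s))


@dataclass(frozen=True)
class SteadyStateResponse:
    """Fixed point (u_inf, R_inf, I_inf) of the per-pulse map at one frequency."""

    u_inf: float
    R_inf: float
    I_inf: float
    frequency: float


class SteadyStateObservations(dict):
    """Mapping ``frequency (Hz) -> observed steady-state peak amplitude``."""

    @classmethod
    def from_arrays(
        cls, frequencies: Sequence[float], amplitudes: Sequence[float]
    ) -> "SteadyStateObservations":
        freqs = np.asarray(frequencies, dtype=float)
        amps = np.asarray(amplitudes, dtype=float)
        if freqs.size != amps.size:
            raise ValueError("frequencies and amplitudes must align")
        if np.unique(freqs).size != freqs.size:
            raise ValueError("frequencies must be distinct")
        return cls(zip(freqs.tolist(), amps.tolist()))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        freqs = np.array(sorted(self), dtype=float)
        amps = np.array([self[f] for f in freqs], dtype=float)
        return freqs, amps


@dataclass
class FitResult:
    """Outcome of a fitting run with its full optimization history.

    ``stage_history`` holds one record per recorded iteration:
    ``(stage label, iteration index, cost, parameter vector [f,U,F,D])``.
    """

    params: TMParameters
    stage_history: list[tuple[str, int, float, np.ndarray]]
    total_cost: float
    config: Mapping[str, object] = field(default_factory=dict)

    def costs(self, stage: str | None = None) -> np.ndarray:
        recs = self.stage_history
        if stage is not None:
            recs = [r for r in recs if r[0] == stage]
        return np.array([r[2] for r in recs], dtype=float)
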