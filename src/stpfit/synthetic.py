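"""Ground-truthed synthetic multi-frequency TM datasets.

Emulates DBS-like constant-frequency stimulation experiments: per-pulse PSC
peak series over several frequencies from a known parameter set, with
additive i.i.d. Gaussian noise whose standard deviation is a fraction of
the maximum absolute clean amplitude over the whole dataset (the 5% / 20%
noise conditions used in validation).
"""

from __future__ import annotations

import numpy as np

from .datatypes import MultiFrequencyDataset, PeakSeries, TMParameters
from .model import peak_values

__all__ = [
    "DEFAULT_RANGES",
    "STANDARD_FREQUENCIES",
    "EXPERIMENTAL_FREQUENCIES",
    "sample_parameters",
    "plasticity_presets",
    "generate_dataset",
    "generate_experimental_dataset",
]

#: Sampling ranges for random ground-truth parameters: f, U uniform;
#: F, D log-uniform (time constants span decades).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "f": (0.05, 0.95),
    "U": (0.05, 0.95),
    "F": (0.05, 1.0),
    "D": (0.05, 1.0),
}

#: The eight-frequency validation protocol (Hz).
STANDARD_FREQUENCIES = (5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 130.0, 200.0)

#: The three clinically motivated stimulation frequencies (Hz); trains of
#: 1 s duration, so 10, 20 and 130 pulses respectively.
EXPERIMENTAL_FREQUENCIES = (10.0, 20.0, 130.0)


def sample_parameters(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    A: float = 1.0,
    tau_syn: float = 0.003,
) -> list[TMParameters]:
    """Draw n reproducible random parameter sets.

    f and U are uniform over their ranges; F and D are log-uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if not lo <= hi or lo <= 0 and name in ("F", "D"):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        f = rng.uniform(*ranges["f"])
        U = rng.uniform(*ranges["U"])
        F = float(np.exp(rng.uniform(np.log(ranges["F"][0]), np.log(ranges["F"][1]))))
        D = float(np.exp(rng.uniform(np.log(ranges["D"][0]), np.log(ranges["D"][1]))))
        out.append(TMParameters(f=f, U=U, F=F, D=D, A=A, tau_syn=tau_syn))
    return out


def plasticity_presets() -> dict[str, TMParameters]:
    """Five named presets spanning strong depression to strong facilitation.

    Depressing synapses have a high baseline release probability and slow
    resource recovery (F < D); facilitating synapses have low baseline
    release, strong per-pulse facilitation and F > D.  The values are
    repository defaults chosen so that the steady-state amplitude at 50 Hz
    and the I_inf(100 Hz)/I_inf(5 Hz) ratio are both monotone along the
    depression-to-facilitation ordering.
    """
    return {
        "strong_depression": TMParameters(f=0.02, U=0.7, F=0.02, D=0.9),
        "depression": TMParameters(f=0.05, U=0.5, F=0.05, D=0.5),
        "mixed": TMParameters(f=0.1, U=0.3, F=0.2, D=0.2),
        "facilitation": TMParameters(f=0.15, U=0.12, F=0.4, D=0.1),
        "strong_facilitation": TMParameters(f=0.3, U=0.05, F=0.8, D=0.05),
    }


def generate_dataset(
    truth: TMParameters,
    frequencies=STANDARD_FREQUENCIES,
    n_pulses: int | dict[float, int] = 100,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    protocol: str = "",
) -> MultiFrequencyDataset:
    """Simulate peak series at each frequency and add amplitude noise.

    ``n_pulses`` may be a single count or a per-frequency mapping.  The
    noise standard deviation is ``noise_sd_frac`` times the maximum
    absolute clean peak over the whole dataset.
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be nonnegative")
    freqs = [float(f) for f in frequencies]
    counts = (
        {f: int(n_pulses[f]) for f in freqs}
        if isinstance(n_pulses, dict)
        else {f: int(n_pulses) for f in freqs}
    )
    for f, c in counts.items():
        if c < 20:
            raise ValueError(
                f"n_pulses={c} at {f} Hz is too short to contain both the "
                "transient and the steady segment (need >= 20)"
            )
    clean = {f: peak_values(truth, f, counts[f]) for f in freqs}
    max_amp = max(float(np.max(np.abs(v))) for v in clean.values())
    rng = np.random.default_rng(seed)
    series = []
    for f in freqs:
        noise = (
            rng.normal(0.0, noise_sd_frac * max_amp, size=counts[f])
            if noise_sd_frac > 0
            else 0.0
        )
        series.append(PeakSeries(frequency=f, peaks=clean[f] + noise))
    return MultiFrequencyDataset(
        series=series,
        truth=truth,
        noise_sd_frac=noise_sd_frac,
        seed=seed,
        protocol=protocol,
    )


def generate_experimental_dataset(
    truth: TMParameters,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
) -> MultiFrequencyDataset:
    """The three-frequency protocol: 10, 20, 130 Hz trains of 1 s duration
    (10, 20 and 130 pulses)."""
    # 1-s trains: a 10 Hz train has only 10 pulses, shorter than the >=20
    # floor generate_dataset enforces, so the series are built directly
    counts = {f: int(round(f * 1.0)) for f in EXPERIMENTAL_FREQUENCIES}
    freqs = list(EXPERIMENTAL_FREQUENCIES)
    clean = {f: peak_values(truth, f, counts[f]) for f in freqs}
    max_amp = max(float(np.max(np.abs(v))) for v in clean.values())
    rng = np.random.default_rng(seed)
    series = []
    for f in freqs:
        noise = (
            rng.normal(0.0, noise_sd_frac * max_amp, size=counts[f])
            if noise_sd_frac > 0
            else 0.0
        )
        series.append(PeakSeries(frequency=f, peaks=clean[f] + noise))
    return MultiFrequencyDataset(
        series=series,
        truth=truth,
        noise_sd_frac=noise_sd_frac,
        seed=seed,
        protocol="experimental",
    )
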