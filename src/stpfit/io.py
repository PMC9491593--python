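"""Plain-text readers and writers for the package's file formats.

Formats:

* parameter files — JSON with keys ``f, U, F_s, D_s, A, tau_syn_s``
* peak-series files — CSV ``frequency_hz,pulse_index,amplitude``
  (1-based pulse index)
* trace files — CSV ``time_s,current``; stimulation times as a one-column
  CSV ``stim_time_s``
* steady-state observations — CSV ``frequency_hz,steady_state_amplitude``
* fit results — JSON with the estimated parameters, frozen set, final cost
  and iteration count
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ContinuousTrace,
    FitResult,
    MultiFrequencyDataset,
    PeakSeries,
    SteadyStateObservations,
    TMParameters,
)

__all__ = [
    "read_parameters",
    "write_parameters",
    "read_peak_series",
    "write_peak_series",
    "read_trace",
    "write_trace",
    "read_stim_times",
    "write_stim_times",
    "read_observations",
    "write_observations",
    "write_fit_result",
]


def read_parameters(path) -> TMParameters:
    with open(path) as fh:
        payload = json.load(fh)
    return TMParameters(
        f=payload["f"],
        U=payload["U"],
        F=payload["F_s"],
        D=payload["D_s"],
        A=payload.get("A", 1.0),
        tau_syn=payload.get("tau_syn_s", 0.003),
    )


def write_parameters(params: TMParameters, path) -> None:
    payload = {
        "f": params.f,
        "U": params.U,
        "F_s": params.F,
        "D_s": params.D,
        "A": params.A,
        "tau_syn_s": params.tau_syn,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_peak_series(path) -> MultiFrequencyDataset:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"frequency_hz", "pulse_index", "amplitude"}
    if not required.issubset(frame.columns):
        raise ValueError(f"peak-series file must have columns {sorted(required)}")
    series = []
    for freq, group in frame.groupby("frequency_hz", sort=True):
        group = group.sort_values("pulse_index")
        idx = group["pulse_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, idx.size + 1)):
            raise ValueError(
                f"pulse_index at {freq} Hz must run 1..n without gaps"
            )
        series.append(
            PeakSeries(frequency=float(freq), peaks=group["amplitude"].to_numpy())
        )
    return MultiFrequencyDataset(series=series)


def write_peak_series(data: MultiFrequencyDataset, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "frequency_hz": s.frequency,
                "pulse_index": np.arange(1, len(s) + 1),
                "amplitude": s.peaks,
            }
        )
        for s in data.series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace(path, stim_path=None) -> ContinuousTrace:
    frame = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "current"}.issubset(frame.columns):
        raise ValueError("trace file must have columns time_s,current")
    stim = read_stim_times(stim_path) if stim_path else np.empty(0)
    return ContinuousTrace(
        times=frame["time_s"].to_numpy(),
        current=frame["current"].to_numpy(),
        stim_times=stim,
    )


def write_trace(trace: ContinuousTrace, path, stim_path=None) -> None:
    pd.DataFrame({"time_s": trace.times, "current": trace.current}).to_csv(
        path, index=False
    )
    if stim_path:
        write_stim_times(trace.stim_times, stim_path)


def read_stim_times(path) -> np.ndarray:
    return pd.read_csv(path, float_precision="round_trip")["stim_time_s"].to_numpy()


def write_stim_times(stim_times, path) -> None:
    pd.DataFrame({"stim_time_s": np.asarray(stim_times)}).to_csv(
        path, index=False
    )


def read_observations(path) -> SteadyStateObservations:
    frame = pd.read_csv(path, float_precision="round_trip")
    if not {"frequency_hz", "steady_state_amplitude"}.issubset(frame.columns):
        raise ValueError(
            "observations file must have columns "
            "frequency_hz,steady_state_amplitude"
        )
    return SteadyStateObservations.from_arrays(
        frame["frequency_hz"].to_numpy(),
        frame["steady_state_amplitude"].to_numpy(),
    )


def write_observations(obs: SteadyStateObservations, path) -> None:
    freqs, amps = obs.arrays()
    pd.DataFrame(
        {"frequency_hz": freqs, "steady_state_amplitude": amps}
    ).to_csv(path, index=False)


def write_fit_result(result: FitResult, path, frozen=()) -> None:
    payload = {
        "parameters": result.params.to_dict(),
        "frozen": sorted(frozen),
        "final_cost": result.total_cost,
        "n_iterations": len(result.stage_history),
        "config": dict(result.config),
        "history": [
            {
                "stage": stage,
                "iteration": it,
                "cost": cost,
                "params": list(map(float, vec)),
            }
            for stage, it, cost, vec in result.stage_history
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
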