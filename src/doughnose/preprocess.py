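"""Trace I/O and signal preprocessing.

Raw chemiresistor signals are normalized to the clean-air baseline (R/R0),
smoothed with a Savitzky-Golay filter, and segmented into the
stabilization / exposure / recovery phases of the measurement cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import CycleSpec, SensorTrace

TRACE_COLUMNS = ["sample_id", "sensor_id", "replicate", "time_s", "resistance_ohm"]

R0_MODES = ("stabilization_mean", "first_sample")


class TraceFormatError(ValueError):
    """The on-disk table does not match the trace CSV dialect."""


class TraceDataError(ValueError):
    """The file parses but violates a trace invariant."""


@dataclass
class NormalizedTrace:
    """Dimensionless R/R0 response series with the baseline used."""

    sample_id: str
    sensor_id: str
    replicate: int
    times: np.ndarray
    response: np.ndarray
    r0: float

    def rate_hz(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PhaseSegments:
    """Half-open index ranges [start, stop) of the three cycle phases."""

    stabilization: range
    exposure: range
    recovery: range

    def __iter__(self):
        return iter((self.stabilization, self.exposure, self.recovery))


def write_traces(traces: list[SensorTrace], path) -> None:
    """Write traces as long-format CSV, values at 12 significant digits."""
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": t.sample_id,
                    "sensor_id": t.sensor_id,
                    "replicate": t.replicate,
                    "time_s": t.times,
                    "resistance_ohm": t.resistance,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_traces(path) -> list[SensorTrace]:
    """Read long-format trace CSV back into trace objects.

    Rows are grouped by (sample_id, sensor_id, replicate) and sorted by
    time; invariant violations raise :class:`TraceDataError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"trace file missing column(s): {', '.join(missing)}")
    traces = []
    for (sample_id, sensor_id, replicate), grp in df.groupby(
        ["sample_id", "sensor_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise TraceDataError(
                f"duplicate time points in trace ({sample_id}, {sensor_id}, {replicate})"
            )
        res = grp["resistance_ohm"].to_numpy(dtype=float)
        if np.any(res <= 0):
            raise TraceDataError(
                f"non-positive resistance in trace ({sample_id}, {sensor_id}, {replicate})"
            )
        traces.append(
            SensorTrace(
                sample_id=str(sample_id),
                sensor_id=str(sensor_id),
                replicate=int(replicate),
                times=times,
                resistance=res,
            )
        )
    return traces


def segment(n_or_trace, cycle: CycleSpec) -> PhaseSegments:
    """Split a trace's index grid into the three cycle phases.

    Accepts a trace (raw or normalized) or an integer length. Boundaries
    are half-open; the recovery segment runs to the end of the trace.
    """
    if isinstance(n_or_trace, (SensorTrace, NormalizedTrace)):
        n = len(n_or_trace.times)
    else:
        n = int(n_or_trace)
    n_stab, n_exp, n_rec = cycle.n_phase_samples()
    if n < n_stab + n_exp + n_rec:
        raise ValueError(
            f"trace has {n} samples, cycle needs {n_stab + n_exp + n_rec}"
        )
    return PhaseSegments(
        stabilization=range(0, n_stab),
        exposure=range(n_stab, n_stab + n_exp),
        recovery=range(n_stab + n_exp, n),
    )


def normalize(
    trace: SensorTrace,
    r0_mode: str = "stabilization_mean",
    cycle: CycleSpec | None = None,
) -> NormalizedTrace:
    """Normalize a resistance trace to its clean-air baseline R0.

    ``stabilization_mean`` (default) uses the mean of the stabilization
    segment, which is robust to sample-level noise; ``first_sample`` uses
    the literal first acquisition value.
    """
    if r0_mode not in R0_MODES:
        raise ValueError(f"r0_mode must be one of {R0_MODES}, got {r0_mode!r}")
    if np.any(trace.resistance <= 0):
        raise ValueError("resistance must be > 0 for normalization")
    if r0_mode == "first_sample":
        r0 = float(trace.resistance[0])
    else:
        cycle = cycle if cycle is not None else CycleSpec()
        seg = segment(trace, cycle)
        r0 = float(trace.resistance[seg.stabilization.start : seg.stabilization.stop].mean())
    if r0 <= 0:
        raise ValueError("baseline R0 must be > 0")
    return NormalizedTrace(
        sample_id=trace.sample_id,
        sensor_id=trace.sensor_id,
        replicate=trace.replicate,
        times=trace.times.copy(),
        response=trace.resistance / r0,
        r0=r0,
    )


def smooth(
    trace: NormalizedTrace, window_s: float = 31.0, polyorder: int = 3
) -> NormalizedTrace:
    """Savitzky-Golay smoothing of the normalized response.

    The window is given in seconds and converted to an odd sample count at
    the trace's rate; mirror padding keeps the output length equal to the
    input. Exact on polynomials of degree <= ``polyorder``.
    """
    rate = trace.rate_hz()
    window = int(round(window_s * rate))
    if window % 2 == 0:
        window += 1
    if window <= polyorder:
        raise ValueError(
            f"SG window of {window} samples must exceed polyorder {polyorder}"
        )
    if window > len(trace.response):
        raise ValueError("SG window larger than the trace")
    # polynomial edge fit keeps output length AND exactness on polynomials
    smoothed = savgol_filter(trace.response, window, polyorder, mode="interp")
    return NormalizedTrace(
        sample_id=trace.sample_id,
        sensor_id=trace.sensor_id,
        replicate=trace.replicate,
        times=trace.times.copy(),
        response=smoothed,
        r0=trace.r0,
    )


def preprocess_trace(
    trace: SensorTrace,
    cycle: CycleSpec | None = None,
    r0_mode: str = "stabilization_mean",
    sg_window_s: float = 31.0,
    sg_polyorder: int = 3,
) -> NormalizedTrace:
    """Standard chain: normalize to R/R0, then Savitzky-Golay smooth."""
    cycle = cycle if cycle is not None else CycleSpec()
    ntrace = normalize(trace, r0_mode=r0_mode, cycle=cycle)
    if np.any(ntrace.response <= 0):
        warnings.warn(
            f"non-positive response after normalization in "
            f"({trace.sample_id}, {trace.sensor_id})",
            stacklevel=2,
        )
    return smooth(ntrace, window_s=sg_window_s, polyorder=sg_polyorder)
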