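"""Per-trace feature extraction for the e-nose response curves.

Fifteen scalar features summarize each preprocessed R/R0 response: four
Sharpe-style variability indices on the leading/trailing 25% and 50% of
the signal, derivative extrema, the Simpson-rule integral, the excursion
range ΔR, the sum of logarithms, the series extrema, the mean of the last
60 samples, the overall mean, the difference between the last-five and
first-five averages, and a signal-to-noise ratio against baseline noise.

Zero-variance segments (which arise on noiseless synthetic traces) yield a
NaN sentinel for the ratio features; callers impute before modelling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.integrate import simpson, trapezoid

from .preprocess import NormalizedTrace, preprocess_trace, segment
from .synthetic import CycleSpec, SampleRecord

#: Canonical feature order: the eleven tabulated signal descriptors first,
#: then the four additional selected statistics.
FEATURE_NAMES = (
    "sharpe_fwd_25",
    "sharpe_back_25",
    "sharpe_fwd_50",
    "sharpe_back_50",
    "min_deriv",
    "max_deriv",
    "integral",
    "delta_r",
    "log_sum",
    "minimum",
    "maximum",
    "mean_last_60",
    "overall_mean",
    "diff_last5_first5",
    "snr",
)

META_COLUMNS = ("sample_id", "replicate", "flour", "phase")


def sharpe(segment_values: np.ndarray) -> float:
    """Mean over sample standard deviation (ddof=1) of a signal segment.

    Scale-invariant variability index; a zero-variance segment returns NaN
    (imputed downstream) rather than raising.
    """
    x = np.asarray(segment_values, dtype=float)
    if x.size < 2:
        raise ValueError("sharpe needs a segment of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        return math.nan
    return float(x.mean() / sd)


def simpson_integral(y: np.ndarray, dx: float = 1.0) -> float:
    """Composite Simpson integral; trapezoid patch on the final interval
    when the interval count is odd (Simpson pairs intervals)."""
    y = np.asarray(y, dtype=float)
    n_intervals = y.size - 1
    if n_intervals < 1:
        raise ValueError("need at least two samples to integrate")
    if n_intervals == 1:
        return float(trapezoid(y, dx=dx))
    if n_intervals % 2 == 0:
        return float(simpson(y, dx=dx))
    return float(simpson(y[:-1], dx=dx) + 0.5 * (y[-2] + y[-1]) * dx)


def compute_features(
    trace: NormalizedTrace, cycle: CycleSpec | None = None
) -> dict[str, float]:
    """All 15 features of one preprocessed response series.

    Leading/trailing segments take floor(0.25 N) and floor(0.5 N) samples;
    derivatives use central differences on the uniform grid (one-sided at
    the ends); SNR divides the overall mean by the sample std of the
    stabilization segment.
    """
    cycle = cycle if cycle is not None else CycleSpec()
    y = np.asarray(trace.response, dtype=float)
    n = y.size
    if n < 60:
        raise ValueError("compute_features needs at least 60 samples")
    if np.any(y <= 0):
        raise ValueError(
            f"non-positive response values in sample {trace.sample_id!r}: "
            "log-sum feature undefined"
        )
    dt = float(trace.times[1] - trace.times[0])
    q25 = max(int(np.floor(0.25 * n)), 2)
    q50 = max(int(np.floor(0.5 * n)), 2)
    deriv = np.gradient(y, dt)
    seg = segment(trace, cycle)
    baseline = y[seg.stabilization.start : seg.stabilization.stop]
    baseline_sd = baseline.std(ddof=1) if baseline.size >= 2 else 0.0
    overall_mean = float(y.mean())
    return {
        "sharpe_fwd_25": sharpe(y[:q25]),
        "sharpe_back_25": sharpe(y[-q25:]),
        "sharpe_fwd_50": sharpe(y[:q50]),
        "sharpe_back_50": sharpe(y[-q50:]),
        "min_deriv": float(deriv.min()),
        "max_deriv": float(deriv.max()),
        "integral": simpson_integral(y, dx=dt),
        "delta_r": float(y.max() - y.min()),
        "log_sum": float(np.log(y).sum()),
        "minimum": float(y.min()),
        "maximum": float(y.max()),
        "mean_last_60": float(y[-60:].mean()),
        "overall_mean": overall_mean,
        "diff_last5_first5": float(y[-5:].mean() - y[:5].mean()),
        "snr": math.nan if baseline_sd == 0 else overall_mean / baseline_sd,
    }


def feature_columns(sensor_ids: list[str]) -> list[str]:
    """Deterministic column order: sensors in given order, features in
    canonical order, named ``{sensor}__{feature}``."""
    return [f"{s}__{f}" for s in sensor_ids for f in FEATURE_NAMES]


def featurize_dataset(
    records: list[SampleRecord],
    cycle: CycleSpec | None = None,
    sensor_ids: list[str] | None = None,
    r0_mode: str = "stabilization_mean",
    sg_window_s: float = 31.0,
    sg_polyorder: int = 3,
    aggregate: str = "none",
) -> pd.DataFrame:
    """Preprocess and featurize every trace of a labelled dataset.

    Returns one row per (sample, replicate cycle) — or per sample with
    ``aggregate="mean"`` — with metadata columns followed by
    ``{sensor}__{feature}`` columns for every configured sensor.
    """
    if aggregate not in ("none", "mean"):
        raise ValueError("aggregate must be 'none' or 'mean'")
    cycle = cycle if cycle is not None else CycleSpec()
    if sensor_ids is None:
        ids: set[str] = set()
        for r in records:
            ids.update(t.sensor_id for t in r.traces)
        sensor_ids = sorted(ids)
    cols = list(META_COLUMNS) + feature_columns(sensor_ids)

    rows = []
    for record in records:
        by_key = {(t.sensor_id, t.replicate): t for t in record.traces}
        for rep in record.replicates:
            missing = [s for s in sensor_ids if (s, rep) not in by_key]
            if missing:
                raise ValueError(
                    f"sample {record.sample_id!r} replicate {rep} is missing "
                    f"sensor trace(s): {', '.join(missing)}"
                )
            row: dict[str, object] = {
                "sample_id": record.sample_id,
                "replicate": rep,
                "flour": record.flour,
                "phase": record.phase,
            }
            for s in sensor_ids:
                ntrace = preprocess_trace(
                    by_key[(s, rep)],
                    cycle=cycle,
                    r0_mode=r0_mode,
                    sg_window_s=sg_window_s,
                    sg_polyorder=sg_polyorder,
                )
                for name, value in compute_features(ntrace, cycle).items():
                    row[f"{s}__{name}"] = value
            rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    if aggregate == "mean" and not df.empty:
        feats = df.groupby(["sample_id", "flour", "phase"], sort=False, as_index=False)[
            feature_columns(sensor_ids)
        ].mean()
        feats.insert(1, "replicate", 0)
        df = feats[cols]
    return df


def impute_median(df: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN sentinels in feature columns by the column median."""
    out = df.copy()
    feat_cols = [c for c in out.columns if "__" in c]
    for c in feat_cols:
        if out[c].isna().any():
            out[c] = out[c].fillna(out[c].median())
    return out
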