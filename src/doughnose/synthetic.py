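"""Synthetic MOS e-nose traces and GC-MS-style VOC presence tables.

The generator emulates the measurement protocol of a triple metal-oxide
chemiresistor array sampling the headspace of leavening dough: each
measurement cycle holds the sensor in clean air (stabilization), exposes it
to the sample headspace (resistance drops as reducing volatiles react with
the oxide surface), then purges with clean air (recovery). Response
amplitudes carry the class signal: fermented (POST) dough emits more
volatiles than unfermented (PRE) dough, and flours of different strength
(W200/W250/W390) imprint different selectivity patterns across the doped
sensor materials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MATERIALS = ("SnO2", "SnO2+Pd", "SnO2+Au")
FLOURS = ("W200", "W250", "W390")
PHASES = ("PRE", "POST", "CONTINUOUS")

#: Chemical classes in decreasing order of abundance in dough headspace.
CHEMICAL_CLASSES = (
    "alkane",
    "alcohol",
    "ester",
    "carboxylic acid",
    "alkene",
    "aldehyde",
    "ketone",
    "ether",
    "amine",
    "alkyne",
    "nitrile",
)


@dataclass(frozen=True)
class CycleSpec:
    """One measurement cycle: stabilization, exposure, recovery.

    Durations are in seconds; sampling at ``rate_hz``. Defaults give the
    standard 100 s + 200 s + 500 s cycle sampled at 1 Hz (800 samples).
    """

    t_stabilize: float = 100.0
    t_expose: float = 200.0
    t_recover: float = 500.0
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_stabilize", "t_expose", "t_recover", "rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CycleSpec.{name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.t_stabilize + self.t_expose + self.t_recover

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.rate_hz))

    def n_phase_samples(self) -> tuple[int, int, int]:
        """Sample counts of the three phases at the cycle's rate."""
        n_stab = int(round(self.t_stabilize * self.rate_hz))
        n_exp = int(round(self.t_expose * self.rate_hz))
        return n_stab, n_exp, self.n_samples - n_stab - n_exp


@dataclass(frozen=True)
class SensorModel:
    """First-order kinetic model of one MOS chemiresistor.

    ``baseline_ohm`` is the clean-air resistance R0. ``tau_response_s`` and
    ``tau_recovery_s`` are the exponential time constants of adsorption and
    desorption. ``drift_per_s`` is a fractional linear baseline drift per
    second; ``noise_cv`` the coefficient of variation of multiplicative
    log-normal measurement noise.
    """

    sensor_id: str
    material: str
    baseline_ohm: float
    tau_response_s: float = 20.0
    tau_recovery_s: float = 60.0
    drift_per_s: float = 0.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(
                f"unknown material {self.material!r}; supported: {MATERIALS}"
            )
        if self.baseline_ohm <= 0:
            raise ValueError("baseline_ohm must be > 0")
        if self.tau_response_s <= 0 or self.tau_recovery_s <= 0:
            raise ValueError("time constants must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class ClassEffect:
    """Response amplitude of one (flour, phase) dough class.

    ``amplitude`` is the fractional resistance drop A in [0, 1) at exposure
    saturation — either one scalar for all sensor materials or a mapping
    material → A. ``amplitude_cv`` is the between-sample (intra-class)
    spread of the amplitude; ``replicate_cv`` the much smaller
    cycle-to-cycle jitter within a sample.
    """

    flour: str
    phase: str
    amplitude: float | dict[str, float]
    amplitude_cv: float = 0.1
    replicate_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.flour not in FLOURS:
            raise ValueError(f"unknown flour {self.flour!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for mat, a in self.amplitude_by_material().items():
            if not 0.0 <= a < 1.0:
                raise ValueError(
                    f"amplitude for {mat} must be in [0, 1), got {a}"
                )
        if self.amplitude_cv < 0 or self.replicate_cv < 0:
            raise ValueError("spread coefficients must be >= 0")

    def amplitude_by_material(self) -> dict[str, float]:
        if isinstance(self.amplitude, dict):
            return dict(self.amplitude)
        return {m: float(self.amplitude) for m in MATERIALS}


@dataclass
class SensorTrace:
    """One sensor's resistance time series for one measurement cycle."""

    sample_id: str
    sensor_id: str
    replicate: int
    times: np.ndarray
    resistance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.times.shape != self.resistance.shape:
            raise ValueError("times and resistance must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError(
                    f"times must be strictly increasing in trace "
                    f"({self.sample_id}, {self.sensor_id}, {self.replicate})"
                )
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("time grid must be uniform")
        if np.any(self.resistance <= 0):
            raise ValueError(
                f"resistance must be > 0 everywhere in trace "
                f"({self.sample_id}, {self.sensor_id}, {self.replicate})"
            )


@dataclass
class SampleRecord:
    """A labelled dough measurement: all traces for one physical sample."""

    sample_id: str
    flour: str
    phase: str
    traces: list[SensorTrace] = field(default_factory=list)

    @property
    def replicates(self) -> list[int]:
        return sorted({t.replicate for t in self.traces})

    @property
    def sensor_ids(self) -> list[str]:
        return sorted({t.sensor_id for t in self.traces})


# --- default study conditions ----------------------------------------------

#: Base fractional resistance drop per dough phase (SnO2 reference sensor).
PHASE_AMPLITUDE = {"PRE": 0.2, "POST": 0.5, "CONTINUOUS": 0.35}

#: Per-material selectivity factors by flour strength: the doped sensors
#: respond differentially to the volatile blend each flour produces, which
#: is what makes flours separable in continuous monitoring.
FLOUR_MATERIAL_PATTERN = {
    "W200": {"SnO2": 1.0, "SnO2+Pd": 0.7, "SnO2+Au": 1.3},
    "W250": {"SnO2": 1.0, "SnO2+Pd": 1.0, "SnO2+Au": 1.0},
    "W390": {"SnO2": 1.0, "SnO2+Pd": 1.3, "SnO2+Au": 0.7},
}

#: Between-sample amplitude spread per flour; the weak flour ferments least
#: reproducibly and shows the greatest intra-class variance.
FLOUR_AMPLITUDE_CV = {"W200": 0.15, "W250": 0.10, "W390": 0.05}

_MAX_AMPLITUDE = 0.95


def default_sensor_models(
    noise_cv: float = 0.05, drift_per_s: float = 0.0
) -> list[SensorModel]:
    """The standard three-element array: SnO2, SnO2+Pd, SnO2+Au."""
    baselines = {"SnO2": 50_000.0, "SnO2+Pd": 80_000.0, "SnO2+Au": 65_000.0}
    return [
        SensorModel(
            sensor_id=f"S{i + 1}",
            material=mat,
            baseline_ohm=baselines[mat],
            noise_cv=noise_cv,
            drift_per_s=drift_per_s,
        )
        for i, mat in enumerate(MATERIALS)
    ]


def default_effect(flour: str, phase: str) -> ClassEffect:
    """Default class effect: phase base amplitude x flour selectivity."""
    base = PHASE_AMPLITUDE[phase]
    pattern = FLOUR_MATERIAL_PATTERN[flour]
    amp = {m: min(base * pattern[m], _MAX_AMPLITUDE) for m in MATERIALS}
    return ClassEffect(
        flour=flour,
        phase=phase,
        amplitude=amp,
        amplitude_cv=FLOUR_AMPLITUDE_CV[flour],
    )


# --- trace simulation -------------------------------------------------------


def response_curve(
    times: np.ndarray,
    cycle: CycleSpec,
    amplitude: float,
    tau_response_s: float,
    tau_recovery_s: float,
) -> np.ndarray:
    """Noiseless normalized response R/R0 of the piecewise kinetic model.

    Baseline 1 during stabilization; saturating exponential drop
    ``1 - A (1 - exp(-(t - t_on)/tau_resp))`` during exposure; exponential
    return toward 1 with ``tau_recovery_s`` afterwards.
    """
    t_on = cycle.t_stabilize
    t_off = cycle.t_stabilize + cycle.t_expose
    y = np.ones_like(times, dtype=float)
    expo = times >= t_on
    y[expo] = 1.0 - amplitude * (1.0 - np.exp(-(times[expo] - t_on) / tau_response_s))
    depth = amplitude * (1.0 - np.exp(-cycle.t_expose / tau_response_s))
    rec = times >= t_off
    y[rec] = 1.0 - depth * np.exp(-(times[rec] - t_off) / tau_recovery_s)
    return y


def simulate_trace(
    model: SensorModel,
    effect: ClassEffect,
    cycle: CycleSpec,
    seed: int | np.random.SeedSequence = 0,
    *,
    sample_id: str = "sample",
    replicate: int = 0,
    amplitude_override: float | None = None,
) -> SensorTrace:
    """Simulate one measurement cycle for one sensor.

    The deterministic kinetic curve is scaled by the class amplitude for the
    sensor's material (or ``amplitude_override`` if given), then a linear
    baseline drift and mean-one multiplicative log-normal noise are applied.
    Deterministic given the seed.
    """
    if amplitude_override is not None:
        amp = float(amplitude_override)
    else:
        amp = effect.amplitude_by_material()[model.material]
    if not 0.0 <= amp < 1.0:
        raise ValueError(f"amplitude must be in [0, 1), got {amp}")

    n = cycle.n_samples
    times = np.arange(n) / cycle.rate_hz
    y = response_curve(times, cycle, amp, model.tau_response_s, model.tau_recovery_s)
    resistance = model.baseline_ohm * y
    resistance = resistance + model.baseline_ohm * model.drift_per_s * times
    if model.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(model.noise_cv**2))
        # mean-one log-normal multiplier keeps the expected curve unbiased
        resistance = resistance * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    return SensorTrace(
        sample_id=sample_id,
        sensor_id=model.sensor_id,
        replicate=replicate,
        times=times,
        resistance=resistance,
    )


def _trace_seed(seed: int, *key: int) -> np.random.SeedSequence:
    # counter-based fan-out: stable per-trace streams under reordering
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def simulate_dataset(
    design: list[tuple[str, str, int, int]],
    models: list[SensorModel] | None = None,
    effects: dict[tuple[str, str], ClassEffect] | None = None,
    cycle: CycleSpec | None = None,
    seed: int = 0,
) -> list[SampleRecord]:
    """Simulate a labelled study: ``design`` rows are
    ``(flour, phase, n_samples, n_replicate_cycles)``.

    Per sample one amplitude factor is drawn (between-sample spread), per
    replicate cycle a small jitter factor, shared across the sensor array;
    each sensor's trace then gets its own noise stream. The default design
    convention is triplicate samples with 10 replicate cycles each.
    """
    models = models if models is not None else default_sensor_models()
    cycle = cycle if cycle is not None else CycleSpec()
    records: list[SampleRecord] = []
    for di, (flour, phase, n_samples, n_reps) in enumerate(design):
        if flour not in FLOURS:
            raise ValueError(f"unknown flour {flour!r}")
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        if n_samples < 1 or n_reps < 1:
            raise ValueError("n_samples and n_replicate_cycles must be >= 1")
        if effects is not None and (flour, phase) in effects:
            effect = effects[(flour, phase)]
        else:
            effect = default_effect(flour, phase)
        amps = effect.amplitude_by_material()
        for si in range(n_samples):
            sample_id = f"{flour}_{phase}_{si + 1}"
            rng_sample = np.random.default_rng(_trace_seed(seed, di, si))
            f_sample = rng_sample.lognormal(
                -0.5 * np.log1p(effect.amplitude_cv**2),
                np.sqrt(np.log1p(effect.amplitude_cv**2)),
            )
            record = SampleRecord(sample_id=sample_id, flour=flour, phase=phase)
            for ri in range(n_reps):
                rng_rep = np.random.default_rng(_trace_seed(seed, di, si, ri))
                f_rep = rng_rep.lognormal(
                    -0.5 * np.log1p(effect.replicate_cv**2),
                    np.sqrt(np.log1p(effect.replicate_cv**2)),
                )
                for ki, model in enumerate(models):
                    a = min(amps[model.material] * f_sample * f_rep, _MAX_AMPLITUDE)
                    trace = simulate_trace(
                        model,
                        effect,
                        cycle,
                        seed=_trace_seed(seed, di, si, ri, 3 + ki),
                        sample_id=sample_id,
                        replicate=ri,
                        amplitude_override=a,
                    )
                    record.traces.append(trace)
            records.append(record)
    return records


def dataset_metadata(records: list[SampleRecord]) -> pd.DataFrame:
    """Label table: one row per sample with flour and phase."""
    return pd.DataFrame(
        [
            {"sample_id": r.sample_id, "flour": r.flour, "phase": r.phase}
            for r in records
        ],
        columns=["sample_id", "flour", "phase"],
    )


# --- VOC presence tables ----------------------------------------------------


def simulate_voc_table(
    n_common: int,
    n_pre_only: int,
    n_post_only: int,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
    flours: tuple[str, ...] = FLOURS,
) -> pd.DataFrame:
    """Build a synthetic compound x condition presence table.

    The pooled (all-flour union) inventory partitions into ``n_common``
    compounds detected in both phases, ``n_pre_only`` only before leavening
    and ``n_post_only`` only after. Each detected compound is assigned a
    random non-empty flour subset per phase; chemical classes are drawn with
    the given weights over the standard class vocabulary.
    """
    for name, n in (
        ("n_common", n_common),
        ("n_pre_only", n_pre_only),
        ("n_post_only", n_post_only),
    ):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    if class_weights is None:
        # geometric taper over the abundance-ordered class vocabulary
        w = 0.6 ** np.arange(len(CHEMICAL_CLASSES))
        class_weights = dict(zip(CHEMICAL_CLASSES, w / w.sum()))
    classes = list(class_weights)
    probs = np.array([class_weights[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    total = n_common + n_pre_only + n_post_only
    memberships = (
        ["both"] * n_common + ["pre_only"] * n_pre_only + ["post_only"] * n_post_only
    )
    rows = []
    for i, membership in enumerate(memberships):
        compound = f"voc-{i + 1:03d}"
        chem = classes[rng.choice(len(classes), p=probs)]
        present_phases = {
            "both": ("PRE", "POST"),
            "pre_only": ("PRE",),
            "post_only": ("POST",),
        }[membership]
        flour_sets = {}
        for ph in present_phases:
            k = int(rng.integers(1, len(flours) + 1))
            chosen = rng.choice(len(flours), size=k, replace=False)
            flour_sets[ph] = {flours[j] for j in chosen}
        for flour, ph in itertools.product(flours, ("PRE", "POST")):
            rows.append(
                {
                    "compound": compound,
                    "chemical_class": chem,
                    "phase": ph,
                    "flour": flour,
                    "present": int(ph in present_phases and flour in flour_sets[ph]),
                }
            )
    columns = ["compound", "chemical_class", "phase", "flour", "present"]
    table = pd.DataFrame(rows, columns=columns)
    assert table["compound"].nunique() == total
    return table
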