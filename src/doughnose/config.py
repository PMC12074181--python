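"""Validated pipeline configuration (YAML-serializable)."""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .synthetic import (
    FLOUR_AMPLITUDE_CV,
    FLOUR_MATERIAL_PATTERN,
    FLOURS,
    MATERIALS,
    PHASE_AMPLITUDE,
    ClassEffect,
    CycleSpec,
    SensorModel,
)

_MAX_AMPLITUDE = 0.95


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CycleConfig(_Strict):
    t_stabilize: float = Field(100.0, gt=0)
    t_expose: float = Field(200.0, gt=0)
    t_recover: float = Field(500.0, gt=0)
    rate_hz: float = Field(1.0, gt=0)


class SensorConfig(_Strict):
    sensor_id: str
    material: Literal["SnO2", "SnO2+Pd", "SnO2+Au"]
    baseline_ohm: float = Field(gt=0)
    tau_response_s: float = Field(20.0, gt=0)
    tau_recovery_s: float = Field(60.0, gt=0)
    drift_per_s: float = 0.0
    noise_cv: float = Field(0.05, ge=0)


class EffectConfig(_Strict):
    """Class-effect scales: phase base amplitudes, per-flour material
    selectivity patterns and amplitude spreads."""

    phase_amplitude: dict[str, float] = Field(
        default_factory=lambda: dict(PHASE_AMPLITUDE)
    )
    flour_material_pattern: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {f: dict(p) for f, p in FLOUR_MATERIAL_PATTERN.items()}
    )
    amplitude_cv: dict[str, float] = Field(
        default_factory=lambda: dict(FLOUR_AMPLITUDE_CV)
    )
    replicate_cv: float = Field(0.02, ge=0)

    @model_validator(mode="after")
    def _check(self):
        for ph, a in self.phase_amplitude.items():
            if not 0 <= a < 1:
                raise ValueError(f"phase_amplitude[{ph}] must be in [0, 1)")
        for f, cv in self.amplitude_cv.items():
            if f not in FLOURS:
                raise ValueError(f"unknown flour {f!r} in amplitude_cv")
            if cv < 0:
                raise ValueError(f"amplitude_cv[{f}] must be >= 0")
        return self


class DesignCell(_Strict):
    flour: Literal["W200", "W250", "W390"]
    phase: Literal["PRE", "POST", "CONTINUOUS"]
    n_samples: int = Field(3, ge=1)
    n_replicate_cycles: int = Field(10, ge=1)


class PreprocessingConfig(_Strict):
    r0_mode: Literal["stabilization_mean", "first_sample"] = "stabilization_mean"
    sg_window_s: float = Field(31.0, gt=0)
    sg_polyorder: int = Field(3, ge=1)


class FeatureConfig(_Strict):
    aggregate: Literal["none", "mean"] = "none"


class ModelConfig(_Strict):
    k_features: int = Field(7, ge=1)
    n_trees: int = Field(300, ge=10)
    n_components_continuous: int = Field(2, ge=1, le=3)
    n_components_prepost: int = Field(3, ge=1, le=3)
    qc_threshold: float = Field(0.10, ge=0)
    k_sigma: float = Field(3.0, gt=0)
    selection: Literal["in_fold", "pre"] = "in_fold"


class VocConfig(_Strict):
    n_common: int = Field(34, ge=0)
    n_pre_only: int = Field(38, ge=0)
    n_post_only: int = Field(36, ge=0)


def _default_sensors() -> list[SensorConfig]:
    baselines = {"SnO2": 50_000.0, "SnO2+Pd": 80_000.0, "SnO2+Au": 65_000.0}
    return [
        SensorConfig(sensor_id=f"S{i + 1}", material=m, baseline_ohm=baselines[m])
        for i, m in enumerate(MATERIALS)
    ]


def _default_design() -> list[DesignCell]:
    cells = [
        DesignCell(flour=f, phase="CONTINUOUS") for f in FLOURS
    ]
    for f in FLOURS:
        cells += [
            DesignCell(flour=f, phase="PRE"),
            DesignCell(flour=f, phase="POST"),
        ]
    return cells


class PipelineConfig(_Strict):
    """Full study configuration; defaults reproduce the standard design:
    triplicate samples x 10 replicate cycles for each flour in CONTINUOUS,
    PRE and POST conditions."""

    cycle: CycleConfig = Field(default_factory=CycleConfig)
    sensors: list[SensorConfig] = Field(default_factory=_default_sensors)
    effects: EffectConfig = Field(default_factory=EffectConfig)
    design: list[DesignCell] = Field(default_factory=_default_design)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    voc: VocConfig = Field(default_factory=VocConfig)
    seed: int = 42

    # --- adapters to the domain objects ---

    def cycle_spec(self) -> CycleSpec:
        return CycleSpec(
            t_stabilize=self.cycle.t_stabilize,
            t_expose=self.cycle.t_expose,
            t_recover=self.cycle.t_recover,
            rate_hz=self.cycle.rate_hz,
        )

    def sensor_models(self) -> list[SensorModel]:
        return [
            SensorModel(
                sensor_id=s.sensor_id,
                material=s.material,
                baseline_ohm=s.baseline_ohm,
                tau_response_s=s.tau_response_s,
                tau_recovery_s=s.tau_recovery_s,
                drift_per_s=s.drift_per_s,
                noise_cv=s.noise_cv,
            )
            for s in self.sensors
        ]

    def class_effects(self) -> dict[tuple[str, str], ClassEffect]:
        effects = {}
        for cell in self.design:
            key = (cell.flour, cell.phase)
            if key in effects:
                continue
            base = self.effects.phase_amplitude[cell.phase]
            pattern = self.effects.flour_material_pattern[cell.flour]
            amp = {m: min(base * pattern[m], _MAX_AMPLITUDE) for m in MATERIALS}
            effects[key] = ClassEffect(
                flour=cell.flour,
                phase=cell.phase,
                amplitude=amp,
                amplitude_cv=self.effects.amplitude_cv[cell.flour],
                replicate_cv=self.effects.replicate_cv,
            )
        return effects

    def design_tuples(self) -> list[tuple[str, str, int, int]]:
        return [
            (c.flour, c.phase, c.n_samples, c.n_replicate_cycles)
            for c in self.design
        ]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
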