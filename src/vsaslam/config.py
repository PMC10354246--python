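"""Experiment configuration with the published default hyperparameters.

The defaults match the reference experiment table: 45,000 path-integrator
neurons (500 per oscillator at d=181), 1,000-neuron grid-cell / object-
vector / associative-memory populations, view radius 0.3x the arena radius,
50 ms synapses, 200-400 Hz maximum rates, 10% active proportion, and the
stated learning rates.  ``scale`` multiplies every neuron count for
desk-scale runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml


@dataclass
class ExperimentConfig:
    d: int = 181
    m: int = 2
    arena_radius: float = 1.0
    length_scale: float = 0.1
    view_radius_frac: float = 0.3

    n_pi: int = 45_000  # total; split uniformly over floor(d/2) oscillators
    n_gc: int = 1_000
    n_ovc: int = 1_000
    n_am: int = 1_000
    n_velocity: int = 500

    tau_syn: float = 0.05
    max_rate_low: float = 200.0
    max_rate_high: float = 400.0
    active_proportion: float = 0.1
    voja_rate: float = 5e-3
    pes_rate: float = 1e-2

    dt: float = 1e-3
    duration: float = 120.0
    cutoff: float = 0.2
    n_landmarks: int = 10

    tier: str = "spiking"  # path-integrator fidelity tier
    scale: float = 1.0  # multiplies neuron counts
    chunk_steps: int = 25  # control/learning cadence in steps
    decode_every: int = 25  # metric decode cadence in steps
    correction_gain: float = 40.0  # 2 per tau_syn; must exceed map plasticity
    map_train_steps: int = 5  # learning steps (of dt each) per attention event
    # prediction-error deadband: skip map updates when the recall already
    # matches the presented value (stops converged entries from bleeding
    # into each other through shared neurons)
    train_deadband_cos: float = 0.9
    train_deadband_norm: float = 0.8
    # active proportion of the velocity-input population; low-dimensional
    # signals need the dense tuning, the sparse table value is for the
    # place-coded populations
    velocity_active_proportion: float = 0.5
    confidence_threshold: float = 0.5
    grid_resolution: int = 101
    encoder_style: str = "random"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        if self.d % 2 == 0:
            raise ValueError("d must be odd")

    @property
    def n_vco(self) -> int:
        return (self.d - 1) // 2

    @property
    def n_per_vco(self) -> int:
        return max(int(round(self.scale * self.n_pi / self.n_vco)), 10)

    @property
    def view_radius(self) -> float:
        return self.view_radius_frac * self.arena_radius

    def scaled(self, name: str) -> int:
        return max(int(round(self.scale * getattr(self, name))), 10)

    @property
    def max_rate_range(self):
        return (self.max_rate_low, self.max_rate_high)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys: {', '.join(bad)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
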