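"""Synthetic arenas and band-limited random trajectories.

Environments are circular (or spherical) arenas with point landmarks whose
identities are composed feature pointers, plus optional wall regions given
as axis-aligned rectangles.  Trajectories are low-pass-filtered Gaussian
noise rescaled into the arena, with velocities from forward differences.
A spiking velocity channel re-encodes the velocity through a neuron
population to produce the realistically noisy input signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import _kernels
from .nef import LIFParams, make_population, solve_decoders
from .vsa import SemanticPointer, Vocabulary, bind


class VocabError(ValueError):
    pass


COLOR_NAMES = ["BLUE", "ORANGE", "RED", "GREEN", "PURPLE", "YELLOW"]
SHAPE_NAMES = ["SQUARE", "TRIANGLE", "CIRCLE", "STAR", "DIAMOND", "CROSS"]


@dataclass
class Landmark:
    position: np.ndarray
    name: str  # e.g. "BLUE*SQUARE"
    composed_of: tuple


@dataclass
class Region:
    """Union of axis-aligned boxes, each an (m, 2) array of lo/hi bounds."""

    name: str
    boxes: list

    def indicator(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        mask = np.zeros(points.shape[0], dtype=bool)
        for box in self.boxes:
            box = np.asarray(box, dtype=float)
            inside = np.all(
                (points >= box[:, 0]) & (points <= box[:, 1]), axis=1
            )
            mask |= inside
        return mask


@dataclass
class Environment:
    m: int
    radius: float
    landmarks: list
    regions: list = dc_field(default_factory=list)
    vocab: Vocabulary | None = None

    def feature_pointer(self, landmark: Landmark) -> SemanticPointer:
        if self.vocab is None:
            raise VocabError("environment has no vocabulary")
        ptr = self.vocab[landmark.composed_of[0]]
        for name in landmark.composed_of[1:]:
            ptr = bind(ptr, self.vocab[name])
        ptr.label = landmark.name
        return ptr

    def landmark_positions(self) -> np.ndarray:
        if not self.landmarks:
            return np.zeros((0, self.m))
        return np.stack([lm.position for lm in self.landmarks])

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "m": self.m,
                "radius": self.radius,
                "landmarks": [
                    {
                        "name": lm.name,
                        "composed_of": list(lm.composed_of),
                        "position": np.asarray(lm.position).tolist(),
                    }
                    for lm in self.landmarks
                ],
                "regions": [
                    {
                        "name": rg.name,
                        "boxes": [np.asarray(b).tolist() for b in rg.boxes],
                    }
                    for rg in self.regions
                ],
            }
        )

    @classmethod
    def from_yaml(cls, text: str, vocab: Vocabulary | None = None) -> "Environment":
        data = yaml.safe_load(text)
        landmarks = [
            Landmark(
                position=np.asarray(lm["position"], dtype=float),
                name=lm["name"],
                composed_of=tuple(lm["composed_of"]),
            )
            for lm in data.get("landmarks", [])
        ]
        regions = [
            Region(name=rg["name"], boxes=[np.asarray(b) for b in rg["boxes"]])
            for rg in data.get("regions", [])
        ]
        return cls(
            m=data["m"],
            radius=data["radius"],
            landmarks=landmarks,
            regions=regions,
            vocab=vocab,
        )


@dataclass
class Trajectory:
    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, m)
    velocities: np.ndarray  # (T, m)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def m(self) -> int:
        return self.positions.shape[1]

    def __len__(self):
        return len(self.times)

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = ["x", "y", "z"][: self.m]
        data = {"t": self.times}
        for i, c in enumerate(cols):
            data[c] = self.positions[:, i]
        for i, c in enumerate(cols):
            data["v" + c] = self.velocities[:, i]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        pos = df[cols].to_numpy(dtype=float)
        vcols = ["v" + c for c in cols]
        if all(c in df.columns for c in vcols):
            vel = df[vcols].to_numpy(dtype=float)
        else:
            dt = float(df["t"].iloc[1] - df["t"].iloc[0])
            vel = np.diff(pos, axis=0, append=pos[-1:]) / dt
            vel[-1] = vel[-2]
        return cls(
            times=df["t"].to_numpy(dtype=float), positions=pos, velocities=vel
        )


def generate_trajectory(
    seed: int,
    duration: float = 120.0,
    dt: float = 1e-3,
    cutoff: float = 0.2,
    radius: float = 1.0,
    m: int = 2,
) -> Trajectory:
    """Band-limited white-noise path inside an arena of the given radius.

    Per-axis Gaussian white noise is brick-wall low-pass filtered at
    ``cutoff`` Hz in the frequency domain, centered, rescaled so the peak
    distance from the origin is 0.95*radius, and differentiated by forward
    differences (last value repeated).
    """
    n_steps = int(round(duration / dt))
    if n_steps < 10:
        raise ValueError("duration/dt must be at least 10")
    nyquist = 0.5 / dt
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist {nyquist} Hz")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, m))
    freqs = np.fft.rfftfreq(n_steps, d=dt)
    spectrum = np.fft.rfft(noise, axis=0)
    spectrum[freqs > cutoff] = 0.0
    spectrum[0] = 0.0  # remove the mean
    pos = np.fft.irfft(spectrum, n=n_steps, axis=0)
    peak = np.linalg.norm(pos, axis=1).max()
    if peak > 0:
        pos *= 0.95 * radius / peak
    vel = np.diff(pos, axis=0) / dt
    vel = np.vstack([vel, vel[-1]])
    times = np.arange(n_steps) * dt
    return Trajectory(times=times, positions=pos, velocities=vel)


def _default_feature_names(n: int):
    combos = [
        (c, s) for s in SHAPE_NAMES for c in COLOR_NAMES
    ]
    if n > len(combos):
        raise VocabError(f"vocabulary supports at most {len(combos)} landmarks")
    return combos[:n]


def make_environment(
    seed: int,
    n_landmarks: int = 10,
    m: int = 2,
    vocab: Vocabulary | None = None,
    radius: float = 1.0,
) -> Environment:
    """Uniformly placed point landmarks with composed color*shape identities."""
    if n_landmarks < 0:
        raise ValueError("n_landmarks must be non-negative")
    rng = np.random.default_rng(seed)
    # uniform in the ball: direction times radius^(1/m) scaling
    dirs = rng.standard_normal((n_landmarks, m))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    dirs /= norms
    radii = radius * 0.9 * rng.uniform(0, 1, size=(n_landmarks, 1)) ** (1.0 / m)
    positions = dirs * radii
    combos = _default_feature_names(n_landmarks)
    if vocab is not None:
        needed = {name for combo in combos for name in combo}
        vocab.populate(sorted(needed))
    landmarks = [
        Landmark(
            position=positions[i],
            name="*".join(combos[i]),
            composed_of=combos[i],
        )
        for i in range(n_landmarks)
    ]
    return Environment(m=m, radius=radius, landmarks=landmarks, vocab=vocab)


WALL_BOXES = [
    np.array([[0.5, 1.1], [-1.1, -0.95]]),
    np.array([[0.95, 1.1], [-1.0, -0.4]]),
]


def worked_example_environment(vocab: Vocabulary) -> Environment:
    """The fixed three-landmark demo arena with an L-shaped wall region.

    Landmarks: blue square at (0.6, 0.2), blue triangle at (0.0, -0.6),
    orange triangle at (-0.2, 0.2); the wall is the union of two rectangles
    hugging the lower-right corner.
    """
    for name in ("BLUE", "ORANGE", "SQUARE", "TRIANGLE", "WALL"):
        if name not in vocab:
            raise VocabError(f"vocabulary is missing symbol {name!r}")
    landmarks = [
        Landmark(np.array([0.6, 0.2]), "BLUE*SQUARE", ("BLUE", "SQUARE")),
        Landmark(np.array([0.0, -0.6]), "BLUE*TRIANGLE", ("BLUE", "TRIANGLE")),
        Landmark(np.array([-0.2, 0.2]), "ORANGE*TRIANGLE", ("ORANGE", "TRIANGLE")),
    ]
    regions = [Region(name="WALL", boxes=[b.copy() for b in WALL_BOXES])]
    return Environment(
        m=2, radius=1.1, landmarks=landmarks, regions=regions, vocab=vocab
    )


def noisy_velocity_channel(
    traj: Trajectory,
    pop_size: int = 500,
    lif: LIFParams | None = None,
    seed: int = 0,
    tau_syn: float = 0.05,
    dt: float | None = None,
) -> np.ndarray:
    """Velocity as decoded from a spiking population (the noisy input signal).

    The trajectory's velocities are encoded by a uniform-sphere population
    and decoded back through identity decoders with a tau-syn low-pass,
    yielding a signal with realistic neural noise.  Returns (T, m).
    """
    if pop_size < 10:
        raise ValueError("pop_size must be at least 10")
    lif = lif or LIFParams(active_proportion=0.5)
    dt = dt or traj.dt
    m = traj.m
    v = traj.velocities
    vmax = float(np.linalg.norm(v, axis=1).max())
    radius = max(vmax * 1.2, 1e-6)
    rng = np.random.default_rng(seed)
    # decoders are solved on the signal's own statistics (velocity samples),
    # with light regularization so shrinkage does not bias the integrator
    pts = v[rng.integers(0, len(v), size=1000)]
    pop = make_population(
        pop_size,
        m,
        encoder_style="uniform-sphere",
        lif=lif,
        seed=seed,
        eval_points=pts,
        radius=radius,
    )
    decoders = solve_decoders(pop, pts, pts, reg=0.02)
    dtype = np.float32
    enc_sc = (pop.gain[:, None] * pop.encoders / radius).astype(dtype)
    out = _kernels.lif_population_run(
        v.astype(dtype),
        enc_sc,
        pop.bias.astype(dtype),
        decoders.astype(dtype),
        dtype(dt),
        dtype(lif.tau_rc),
        dtype(lif.tau_ref),
        dtype(1.0 - np.exp(-dt / tau_syn)),
    )
    return out.astype(float)
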