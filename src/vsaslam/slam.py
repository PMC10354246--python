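"""Landmark perception, the learned environment map, and loop closure.

Landmarks within the view radius are observed with exact displacements
(perception is idealized; identity and distance arrive as direct input).
The displacement encoding is bound with the self-position estimate to give
an allocentric landmark-location estimate, which trains a heteroassociative
memory keyed by the landmark's composed feature pointer (error-driven
decoder learning plus activity-gated encoder adaptation).  On re-encounter,
the memory's recall is unbound from the egocentric observation to produce
an alternative self-position whose difference from the integrator's
estimate is the loop-closure correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nef import (
    LIFParams,
    Population,
    make_population,
    pes_update,
    voja_update,
)
from .ssp import ProbabilityReadout, SSPEncoder
from .vsa import SemanticPointer, Vocabulary, bind, inverse


@dataclass
class LandmarkObservation:
    index: int
    feature: SemanticPointer
    displacement: np.ndarray  # x_i - x(t)
    in_view: bool


def observe(env, x, view_radius: float) -> list:
    """All landmarks within the closed view ball around x, exact displacements."""
    x = np.asarray(x, dtype=float)
    out = []
    for i, lm in enumerate(env.landmarks):
        disp = np.asarray(lm.position, dtype=float) - x
        if np.linalg.norm(disp) <= view_radius:
            out.append(
                LandmarkObservation(
                    index=i,
                    feature=env.feature_pointer(lm),
                    displacement=disp,
                    in_view=True,
                )
            )
    return out


@dataclass
class OVCPopulation:
    """Neurons tuned to encoded agent-to-landmark displacements."""

    pop: Population
    enc: SSPEncoder
    view_radius: float

    @classmethod
    def build(
        cls,
        enc: SSPEncoder,
        view_radius: float,
        n: int = 1000,
        lif: LIFParams | None = None,
        seed: int = 0,
    ) -> "OVCPopulation":
        rng = np.random.default_rng(seed)
        dirs = rng.standard_normal((n, enc.m))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        offsets = dirs * view_radius * rng.uniform(0, 1, (n, 1)) ** (1.0 / enc.m)
        pop = make_population(
            n,
            enc.d,
            encoder_style="provided",
            encoders=enc.encode_vec(offsets),
            lif=lif or LIFParams(),
            seed=seed,
            eval_points=enc.encode_vec(
                dirs[: min(n, 500)] * view_radius
                * rng.uniform(0, 1, (min(n, 500), 1)) ** (1.0 / enc.m)
            ),
        )
        return cls(pop=pop, enc=enc, view_radius=view_radius)


def ovc_encode(enc: SSPEncoder, obs: list, ovc: OVCPopulation | None = None):
    """Egocentric displacement encodings for in-view landmarks.

    Returns (list of (d,) vectors, activities of the attended landmark's
    encoding if a population is given, else None).  The attended landmark is
    the first in the list; callers cycle the list for round-robin attention.
    """
    vecs = [enc.encode_vec(o.displacement) for o in obs]
    acts = None
    if ovc is not None and vecs:
        acts = ovc.pop.rates(vecs[0])
    return vecs, acts


def ol_bind(pi_estimate: np.ndarray, egocentric: np.ndarray) -> np.ndarray:
    """Allocentric landmark-location estimate: bind self-position with offset."""
    return np.asarray(bind(pi_estimate, egocentric))


class AssocMemory:
    """Heteroassociative memory: one population, learned in and out maps.

    Encoders adapt toward presented keys (activity-gated, normalized);
    output decoders follow the error between recall and the presented
    value.  With the learning gate off, recall is a pure deterministic
    function of the query.
    """

    def __init__(
        self,
        key_dim: int,
        value_dim: int,
        n: int = 1000,
        lif: LIFParams | None = None,
        seed: int = 0,
        pes_rate: float = 1e-2,
        voja_rate: float = 5e-3,
    ):
        self.lif = lif or LIFParams()
        # keys live on the unit sphere: intercepts are solved from dot
        # products with random unit vectors so ~active_proportion respond
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((1000, key_dim))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        self.pop = make_population(
            n,
            key_dim,
            encoder_style="uniform-sphere",
            lif=self.lif,
            seed=seed,
            eval_points=pts,
        )
        self.decoders = np.zeros((n, value_dim))
        self.pes_rate = pes_rate
        self.voja_rate = voja_rate
        self.key_dim = key_dim
        self.value_dim = value_dim
        self.learning_gate = False

    def activities(self, query) -> np.ndarray:
        return self.pop.rates(np.asarray(query, dtype=float))

    def recall(self, query) -> np.ndarray:
        """Deterministic decoded output for a query (works untrained: zeros)."""
        return self.activities(query) @ self.decoders

    def train_step(self, key, value, dt: float = 1e-3, n_steps: int = 1):
        """Gated learning: encoder shift toward the key, decoder descent on
        (recall - value).  No-op when the gate is off."""
        if not self.learning_gate:
            return self
        key = np.asarray(key, dtype=float)
        value = np.asarray(value, dtype=float)
        for _ in range(n_steps):
            acts = self.activities(key)
            voja_update(self.pop.encoders, acts, key, self.voja_rate, dt)
            acts = self.activities(key)
            error = acts @ self.decoders - value
            pes_update(self.decoders, error, acts, self.pes_rate, dt)
        return self

    def active_fraction(self, query) -> float:
        return float(np.mean(self.activities(query) > 0))

    def save(self, path) -> None:
        from .nef import save_population

        save_population(self.pop, path, decoders=self.decoders)

    @classmethod
    def load(cls, path, pes_rate: float = 1e-2, voja_rate: float = 5e-3):
        from .nef import load_population

        pop, decoders = load_population(path)
        mem = cls.__new__(cls)
        mem.lif = pop.lif
        mem.pop = pop
        mem.decoders = decoders
        mem.pes_rate = pes_rate
        mem.voja_rate = voja_rate
        mem.key_dim = pop.dim
        mem.value_dim = decoders.shape[1]
        mem.learning_gate = False
        return mem


def am_train_step(mem: AssocMemory, key, value, dt: float = 1e-3):
    return mem.train_step(key, value, dt)


def am_recall(mem: AssocMemory, query) -> np.ndarray:
    return mem.recall(query)


def reverse_recall(mem2: AssocMemory, location_query, vocab_features: dict) -> list:
    """Rank feature pointers by similarity to the recalled vector.

    ``vocab_features`` maps name -> pointer (e.g. every composed landmark
    identity).  Scores are dot products against unit-normalized feature
    pointers; the recall's own magnitude is kept, so a weak recall (query
    over an empty area) scores low everywhere instead of being renormalized
    into a spurious confident match.  Returns [(name, score), ...] sorted
    descending.
    """
    out_vec = mem2.recall(location_query)
    scores = []
    for name, ptr in vocab_features.items():
        p = np.asarray(ptr, dtype=float)
        pn = np.linalg.norm(p)
        scores.append((name, float(np.dot(out_vec, p) / pn) if pn else 0.0))
    scores.sort(key=lambda kv: -kv[1])
    return scores


def vector_to_landmark(pi_estimate, recalled_location) -> np.ndarray:
    """Egocentric vector estimate: unbind self-position from a recalled location."""
    return np.asarray(bind(inverse(np.asarray(pi_estimate)), recalled_location))


@dataclass
class LoopClosureState:
    confidence_threshold: float = 0.5
    valid: bool = False
    correction: np.ndarray | None = None
    alt_position: np.ndarray | None = None


def loop_closure(
    state: LoopClosureState,
    obs: LandmarkObservation | None,
    mem: AssocMemory,
    ovc_ssp: np.ndarray | None,
    pi_estimate: np.ndarray,
    readout: ProbabilityReadout,
) -> LoopClosureState:
    """Recall-based correction of the self-position estimate.

    If a landmark is in view and the memory's recall for its key carries
    confidence (peak lattice similarity above threshold), the alternative
    self-position is the recall unbound from the egocentric observation,
    and the correction is its difference from the integrator estimate.
    """
    state.valid = False
    state.correction = np.zeros(len(pi_estimate))
    state.alt_position = None
    if obs is None or not obs.in_view or ovc_ssp is None:
        return state
    recall = mem.recall(obs.feature)
    confidence = float(readout.field(recall).max())
    if confidence <= state.confidence_threshold:
        return state
    alt = np.asarray(bind(recall, inverse(ovc_ssp)))
    norm = np.linalg.norm(alt)
    if norm > 0.3:
        # renormalize: a partially-trained recall has sub-unit magnitude and
        # would otherwise drag the estimate off the unit-spectrum manifold
        alt = alt / norm
    state.valid = True
    state.alt_position = alt
    state.correction = alt - np.asarray(pi_estimate, dtype=float)
    return state


def map_export(
    mem: AssocMemory,
    env,
    readout: ProbabilityReadout,
) -> list:
    """Decoded location and confidence for every landmark key in the map."""
    out = []
    for lm in env.landmarks:
        key = env.feature_pointer(lm)
        recall = mem.recall(key)
        field = readout.field(recall)
        confidence = float(field.max())
        try:
            loc = readout.map_decode(recall).tolist()
        except Exception:
            loc = None
        out.append({"key": lm.name, "decoded": loc, "confidence": confidence})
    return out
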