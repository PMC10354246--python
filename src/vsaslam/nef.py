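"""Minimal Neural Engineering Framework runtime.

Populations of leaky integrate-and-fire neurons encode vectors through
gain/bias/encoder tuning curves; decoded connections are solved by ridge
regression on rate-mode activities; first-order low-pass synapses filter
decoded values; the dynamics transform wraps a target state equation so the
filtered recurrent loop realizes it.  Error-driven decoder learning and
activity-gated encoder learning are provided for the associative memory.

Three fidelity tiers share one semantics: ``ideal`` (state equations, no
neurons), ``rate`` (steady-state tuning curves), and ``spiking`` (voltage
stepping with refractory clamping, spike amplitude 1/dt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class TuningError(ValueError):
    pass


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron constants (normalized threshold 1)."""

    tau_rc: float = 0.02
    tau_ref: float = 0.002
    max_rate_range: tuple = (200.0, 400.0)
    active_proportion: float = 0.1

    def __post_init__(self):
        if self.tau_rc <= 0 or self.tau_ref <= 0:
            raise ValueError("time constants must be positive")
        if not (0 < self.max_rate_range[0] <= self.max_rate_range[1]):
            raise ValueError("max rate range must be positive and ordered")


def lif_rate(params: LIFParams, J):
    """Steady-state firing rate (Hz) for input current J (threshold at 1)."""
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    above = J > 1.0 + 1e-12
    Ja = J[above]
    out[above] = 1.0 / (
        params.tau_ref - params.tau_rc * np.log1p(-1.0 / Ja)
    )
    return out if out.ndim else float(out)


def max_rate_current(params: LIFParams, rate) -> np.ndarray:
    """Current at which an LIF neuron fires at ``rate`` Hz (inverse of lif_rate)."""
    rate = np.asarray(rate, dtype=float)
    return 1.0 / (1.0 - np.exp((params.tau_ref - 1.0 / rate) / params.tau_rc))


@dataclass
class Population:
    """A tuned ensemble: unit-norm encoders, positive gains, biases."""

    n: int
    dim: int
    encoders: np.ndarray  # (n, dim), unit rows
    gain: np.ndarray  # (n,)
    bias: np.ndarray  # (n,)
    lif: LIFParams
    radius: float = 1.0
    mode: str = "rate"
    intercepts: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.gain <= 0):
            raise TuningError("gains must be positive")

    def current(self, value) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        if value.shape[-1] != self.dim:
            raise ValueError(
                f"value of dimension {value.shape[-1]}, population expects {self.dim}"
            )
        return self.gain * (value @ self.encoders.T) / self.radius + self.bias

    def rates(self, value) -> np.ndarray:
        """Rate-mode activities for one value (dim,) or a batch (k, dim)."""
        return lif_rate(self.lif, self.current(value))

    def spiking_state(self) -> "SpikingState":
        return SpikingState(
            voltage=np.zeros(self.n), refractory=np.zeros(self.n)
        )

    def step_spikes(self, state: "SpikingState", value, dt: float) -> np.ndarray:
        """Advance membrane voltages one step; returns spikes scaled by 1/dt."""
        J = self.current(value)
        return lif_spike_step(
            state.voltage, state.refractory, J, dt, self.lif.tau_rc, self.lif.tau_ref
        )


@dataclass
class SpikingState:
    voltage: np.ndarray
    refractory: np.ndarray


def lif_spike_step(voltage, refractory, J, dt, tau_rc, tau_ref):
    """Zero-order-hold LIF voltage update (in place), spike amplitude 1/dt.

    Spike times are resolved within the step from the threshold overshoot so
    realized long-run rates are unbiased with respect to :func:`lif_rate`.
    """
    refractory -= dt
    delta = np.clip(dt - refractory, 0.0, dt)
    refractory[:] = np.maximum(refractory, 0.0)
    decay = np.exp(-delta / tau_rc)
    voltage *= decay
    voltage += (1.0 - decay) * J
    spiked = voltage > 1.0
    t_spike = dt + tau_rc * np.log1p(
        -(voltage[spiked] - 1.0) / (J[spiked] - 1.0)
    )
    refractory[spiked] = tau_ref + t_spike
    voltage[spiked] = 0.0
    out = np.zeros_like(voltage)
    out[spiked] = 1.0 / dt
    return out


def make_population(
    n: int,
    dim: int,
    encoder_style: str = "uniform-sphere",
    lif: LIFParams | None = None,
    seed: int = 0,
    encoders: np.ndarray | None = None,
    eval_points: np.ndarray | None = None,
    ssp_encoder=None,
    radius: float = 1.0,
    mode: str = "rate",
) -> Population:
    """Solve per-neuron gains and biases from max rates and intercepts.

    Each neuron is silent at its intercept (current exactly at threshold)
    and fires at its sampled maximum rate when the normalized encoder dot
    product reaches 1.  Intercepts are per-neuron quantiles of the encoder
    projections over representative inputs so that on average
    ``active_proportion`` of the population responds to a random input.
    """
    if n < 1:
        raise TuningError("population needs at least one neuron")
    lif = lif or LIFParams()
    rng = np.random.default_rng(seed)

    if encoder_style == "provided":
        if encoders is None:
            raise TuningError("encoder_style='provided' requires encoders")
        E = np.asarray(encoders, dtype=float)
    elif encoder_style == "uniform-sphere":
        E = rng.standard_normal((n, dim))
    elif encoder_style == "ssp-points":
        if ssp_encoder is None:
            raise TuningError("encoder_style='ssp-points' requires ssp_encoder")
        lo, hi = ssp_encoder.domain_bounds[:, 0], ssp_encoder.domain_bounds[:, 1]
        pts = rng.uniform(lo, hi, size=(n, ssp_encoder.m))
        E = ssp_encoder.encode_vec(pts)
    else:
        raise TuningError(f"unknown encoder style {encoder_style!r}")
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise TuningError("zero-norm encoder row")
    E = E / norms

    if eval_points is None:
        # representative inputs: uniform in the ball of the stated radius
        pts = rng.standard_normal((max(500, 2 * n), dim))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.uniform(0, 1, size=(pts.shape[0], 1)) ** (1.0 / dim)
        eval_points = pts
    proj = (E @ np.asarray(eval_points, dtype=float).T) / radius  # (n, k)
    # per-neuron quantile levels spread around the target proportion:
    # identical intercepts would collapse the population onto a handful of
    # distinct tuning curves and floor the decode error
    p = lif.active_proportion
    levels = rng.uniform(
        max(0.0, 1.0 - 1.5 * p), min(1.0 - 0.5 * p, 0.995), size=n
    )
    intercepts = np.array(
        [np.quantile(proj[i], levels[i]) for i in range(n)]
    )
    intercepts = np.clip(intercepts, -0.999, 0.9)

    max_rates = rng.uniform(*lif.max_rate_range, size=n)
    J_max = max_rate_current(lif, max_rates)
    gain = (J_max - 1.0) / (1.0 - intercepts)
    bias = 1.0 - gain * intercepts
    if np.any(~np.isfinite(gain)) or np.any(gain <= 0):
        raise TuningError("unsatisfiable rate/intercept combination")
    return Population(
        n=n,
        dim=dim,
        encoders=E,
        gain=gain,
        bias=bias,
        lif=lif,
        radius=radius,
        mode=mode,
        intercepts=intercepts,
        seed=seed,
    )


def activities(pop: Population, value) -> np.ndarray:
    return pop.rates(value)


def solve_decoders(
    pop: Population,
    eval_points: np.ndarray,
    targets: np.ndarray,
    reg: float = 0.1,
) -> np.ndarray:
    """Ridge-regression decoders on the rate-mode activity matrix.

    ``reg`` scales the regularization as a fraction of the peak activity
    (the field-standard choice).  Returns (n, dim_out).
    """
    eval_points = np.asarray(eval_points, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    if eval_points.shape[0] < targets.shape[1]:
        raise ValueError("need at least dim_out evaluation points")
    A = pop.rates(eval_points)  # (k, n)
    amax = A.max()
    if amax == 0:
        warnings.warn("all-silent activity matrix; returning zero decoders")
        return np.zeros((pop.n, targets.shape[1]))
    sigma = reg * amax
    k = A.shape[0]
    G = A.T @ A + k * sigma**2 * np.eye(pop.n)
    Y = A.T @ targets
    try:
        import scipy.linalg as sla

        decoders = sla.solve(G, Y, assume_a="pos")
    except Exception:
        warnings.warn("rank-deficient activity Gram matrix; using minimum norm")
        decoders = np.linalg.pinv(G) @ Y
    return decoders


@dataclass
class Lowpass:
    """First-order low-pass synapse state y' = (u - y)/tau, discretized exactly."""

    tau: float
    value: np.ndarray | float = 0.0

    def step(self, u, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        a = np.exp(-dt / self.tau)
        self.value = a * self.value + (1.0 - a) * np.asarray(u, dtype=float)
        return self.value


def synapse_step(state: Lowpass, u, dt: float):
    return state.step(u, dt)


def dynamics_transform(f, g, tau: float):
    """Maps to wire through a tau synapse so the loop computes x' = f(x)+g(u)."""
    f = f or (lambda x: np.zeros_like(np.asarray(x, dtype=float)))
    g = g or (lambda u: np.zeros_like(np.asarray(u, dtype=float)))
    recurrent = lambda x: tau * np.asarray(f(x), dtype=float) + np.asarray(x, float)
    inp = lambda u: tau * np.asarray(g(u), dtype=float)
    return recurrent, inp


@dataclass
class PESConfig:
    kappa: float = 1e-2


@dataclass
class VojaConfig:
    kappa: float = 5e-3


@dataclass
class Connection:
    """A decoded, filtered projection out of a population.

    ``decoders`` is (n, dim_out).  The dense-weight form of the projection
    into a target population factorizes as
    ``w[j, i] = gain[j] * (target.encoders[j] . decoders[i])``.
    """

    source: Population
    decoders: np.ndarray
    synapse: Lowpass | None = None
    tau_syn: float = 0.05
    pes: PESConfig | None = None
    voja: VojaConfig | None = None
    target: Population | None = None

    def __post_init__(self):
        if self.synapse is None:
            self.synapse = Lowpass(self.tau_syn)

    def decode(self, value) -> np.ndarray:
        a = self.source.rates(value)
        return a @ self.decoders

    def step(self, value, dt: float) -> np.ndarray:
        return self.synapse.step(self.decode(value), dt)

    def dense_weights(self) -> np.ndarray:
        if self.target is None:
            raise ValueError("dense weights require a target population")
        return (self.target.gain[:, None] * self.target.encoders) @ self.decoders.T


def save_population(pop: Population, path, decoders: np.ndarray | None = None):
    """Checkpoint tuning parameters (and optional decoders) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n"] = pop.n
        fh.attrs["dim"] = pop.dim
        fh.attrs["radius"] = pop.radius
        fh.attrs["mode"] = pop.mode
        fh.attrs["tau_rc"] = pop.lif.tau_rc
        fh.attrs["tau_ref"] = pop.lif.tau_ref
        fh.attrs["max_rate_low"] = pop.lif.max_rate_range[0]
        fh.attrs["max_rate_high"] = pop.lif.max_rate_range[1]
        fh.attrs["active_proportion"] = pop.lif.active_proportion
        fh.create_dataset("encoders", data=pop.encoders)
        fh.create_dataset("gain", data=pop.gain)
        fh.create_dataset("bias", data=pop.bias)
        if decoders is not None:
            fh.create_dataset("decoders", data=decoders)


def load_population(path):
    """Inverse of :func:`save_population`; returns (Population, decoders|None)."""
    import h5py

    with h5py.File(path, "r") as fh:
        lif = LIFParams(
            tau_rc=float(fh.attrs["tau_rc"]),
            tau_ref=float(fh.attrs["tau_ref"]),
            max_rate_range=(
                float(fh.attrs["max_rate_low"]),
                float(fh.attrs["max_rate_high"]),
            ),
            active_proportion=float(fh.attrs["active_proportion"]),
        )
        pop = Population(
            n=int(fh.attrs["n"]),
            dim=int(fh.attrs["dim"]),
            encoders=fh["encoders"][...],
            gain=fh["gain"][...],
            bias=fh["bias"][...],
            lif=lif,
            radius=float(fh.attrs["radius"]),
            mode=str(fh.attrs["mode"]),
        )
        decoders = fh["decoders"][...] if "decoders" in fh else None
    return pop, decoders


def pes_update(
    decoders: np.ndarray,
    error: np.ndarray,
    acts: np.ndarray,
    kappa: float,
    dt: float,
) -> np.ndarray:
    """One error-driven decoder step (in place); returns the decoders.

    ``error`` is (decoded output - target); the update descends it.  The
    rate is scaled by dt and by 1/n so the effective speed is independent of
    population size, matching ecosystem convention.
    """
    n = decoders.shape[0]
    decoders -= (kappa * dt / n) * np.outer(acts, error)
    return decoders


def voja_update(
    encoders: np.ndarray,
    acts: np.ndarray,
    value: np.ndarray,
    kappa: float,
    dt: float,
) -> np.ndarray:
    """Activity-gated encoder shift toward the input (in place, renormalized)."""
    active = acts > 0
    if np.any(active):
        encoders[active] += (
            kappa * dt * acts[active, None] * (value[None, :] - encoders[active])
        )
        norms = np.linalg.norm(encoders[active], axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        encoders[active] /= norms
    return encoders
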