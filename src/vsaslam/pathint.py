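"""Velocity-controlled-oscillator path integration.

Self-position is carried as the half-spectrum of its encoded vector.  Each
Fourier coefficient is an independent planar oscillator whose frequency is
a row of the encoding matrix dotted with the velocity; a radial term makes
the unit circle attracting so the assembled vector stays near unit length.
Tiers: ``ideal`` integrates the state equations with RK4; ``rate`` and
``spiking`` run one tuned neuron population per oscillator, representing
(frequency, Re, Im), with the dynamics realized through the recurrent
low-pass loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .nef import LIFParams, Population, lif_rate, make_population, solve_decoders
from .ssp import SSP, DecodeFailure, ProbabilityReadout, SSPEncoder


class SingularRadiusError(ValueError):
    pass


def velocity_to_frequencies(enc: SSPEncoder, xdot) -> np.ndarray:
    """Per-oscillator angular frequencies (rad/s): half-spectrum rows dot velocity."""
    xdot = np.asarray(xdot, dtype=float)
    if xdot.shape[-1] != enc.m:
        raise ValueError(f"velocity of dimension {xdot.shape[-1]}, expected {enc.m}")
    return xdot @ enc.A_half.T


def vco_derivative(omega: float, re: float, im: float) -> tuple[float, float]:
    """Stabilized oscillator field: rotation at omega plus radial attraction to 1."""
    r = np.hypot(re, im)
    if r == 0:
        raise SingularRadiusError("oscillator radius is zero")
    s = (1.0 - r * r) / r
    return (-omega * im + s * re, omega * re + s * im)


def _stabilized_field(z: np.ndarray, omega: np.ndarray, r_floor: float = 1e-3):
    """Vectorized complex form of the oscillator field, dz = i*omega*z + s*z."""
    r = np.abs(z)
    r = np.maximum(r, r_floor)
    return 1j * omega * z + ((1.0 - r * r) / r) * z


@dataclass
class VCOTuning:
    """Tuned arrays for a bank of oscillator populations (one per coefficient)."""

    enc_sc: np.ndarray  # (nv, n, 3) gain-scaled encoders
    bias: np.ndarray  # (nv, n)
    dec: np.ndarray  # (nv, n, 4): recurrent (Re, Im) then output (Re, Im)
    encoders: np.ndarray  # (nv, n, 3) unit rows, for firing-map analysis
    gain: np.ndarray
    radius: float
    omega_scale: float


def _solve_vco_tuning(
    n_half: int,
    n_per_vco: int,
    omega_scale: float,
    tau_syn: float,
    lif: LIFParams,
    seed: int,
    radius: float = 1.6,
    n_eval: int = 3000,
    reg: float = 0.1,
    r_floor: float = 0.3,
    dt: float = 1e-3,
    eval_style: str = "ball",
    dtype=np.float32,
) -> VCOTuning:
    """Tune every oscillator population and solve its decoders.

    ``eval_style="ball"`` (default) samples evaluation points uniformly in
    the representational ball — standard practice, which leaves the drift
    characteristic of neural oscillator banks.  ``"annulus"`` concentrates
    points on the operating annulus (oscillator radius near 1) and, with a
    small ``reg``, gives a markedly lower-drift bank at the cost of
    robustness away from the attractor.

    The recurrent decode targets tau*f + identity on (Re, Im); a second
    decode reads the represented (Re, Im) out.  The tau factor is
    compensated for the zero-order-hold discretization of the synapse —
    (1-exp(-dt/tau))*tau_eff equals dt exactly — which otherwise lags every
    oscillator by about dt/(2*tau) in relative frequency.
    """
    rng = np.random.default_rng(seed)
    if eval_style == "annulus":
        rr = np.clip(rng.normal(1.0, 0.05, size=n_eval), 0.5, 1.5)
        th = rng.uniform(0, 2 * np.pi, size=n_eval)
        # frequencies concentrate near zero in operation; uniform tails
        w = np.where(
            rng.uniform(size=n_eval) < 0.7,
            np.clip(rng.normal(0.0, 0.2, size=n_eval), -1.3, 1.3),
            rng.uniform(-1.3, 1.3, size=n_eval),
        )
        eval_points = np.stack([w, rr * np.cos(th), rr * np.sin(th)], axis=1)
    elif eval_style == "ball":
        pts = rng.standard_normal((n_eval, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * 0.95 * rng.uniform(0, 1, (n_eval, 1)) ** (1.0 / 3)
        eval_points = pts
    else:
        raise ValueError(f"unknown eval_style {eval_style!r}")
    # oscillator populations decode a product nonlinearity; they need dense
    # activity, unlike the sparse place-coded populations
    from dataclasses import replace

    lif = replace(lif, active_proportion=0.5)

    re, im = eval_points[:, 1], eval_points[:, 2]
    r = np.maximum(np.hypot(re, im), r_floor)
    s = (1.0 - r * r) / r
    omega = eval_points[:, 0] * omega_scale
    f_re = -omega * im + s * re
    f_im = omega * re + s * im
    tau_eff = dt / (1.0 - np.exp(-dt / tau_syn))
    targets = np.stack(
        [tau_eff * f_re + re, tau_eff * f_im + im, re, im], axis=1
    )

    enc_sc = np.empty((n_half, n_per_vco, 3), dtype=dtype)
    encoders = np.empty((n_half, n_per_vco, 3), dtype=dtype)
    bias = np.empty((n_half, n_per_vco), dtype=dtype)
    gain = np.empty((n_half, n_per_vco), dtype=dtype)
    dec = np.empty((n_half, n_per_vco, 4), dtype=dtype)
    seeds = np.random.SeedSequence(seed).spawn(n_half)
    for v in range(n_half):
        pop = make_population(
            n_per_vco,
            3,
            encoder_style="uniform-sphere",
            lif=lif,
            seed=int(seeds[v].generate_state(1)[0]),
            eval_points=eval_points,
            radius=radius,
        )
        dv = solve_decoders(pop, eval_points, targets, reg=reg)
        enc_sc[v] = (pop.gain[:, None] * pop.encoders / radius).astype(dtype)
        encoders[v] = pop.encoders.astype(dtype)
        bias[v] = pop.bias.astype(dtype)
        gain[v] = pop.gain.astype(dtype)
        dec[v] = dv.astype(dtype)
    return VCOTuning(
        enc_sc=enc_sc,
        bias=bias,
        dec=dec,
        encoders=encoders,
        gain=gain,
        radius=radius,
        omega_scale=omega_scale,
    )


class PathIntegrator:
    """A bank of floor(d/2) oscillators holding a self-position estimate.

    Use :func:`pi_init` to construct one.  The DC coefficient is pinned to
    the constant 1 and not simulated.
    """

    def __init__(
        self,
        enc: SSPEncoder,
        tier: str = "ideal",
        n_per_vco: int = 500,
        tau_syn: float = 0.05,
        lif: LIFParams | None = None,
        seed: int = 0,
        omega_scale: float | None = None,
        correction_gain: float = 4.0,
        dt: float = 1e-3,
        tuning: VCOTuning | None = None,
        eval_style: str = "ball",
        reg: float = 0.1,
    ):
        if tier not in ("ideal", "rate", "spiking"):
            raise ValueError(f"unknown tier {tier!r}")
        self.enc = enc
        self.tier = tier
        self.n_vco = enc.n_half
        self.tau_syn = tau_syn
        self.correction_gain = correction_gain
        self.lif = lif or LIFParams()
        self.seed = seed
        if omega_scale is None:
            # normalize frequencies by the largest one reachable at unit speed
            omega_scale = float(np.linalg.norm(enc.A_half, axis=1).max()) * 0.5
        self.omega_scale = omega_scale
        self.n_per_vco = n_per_vco

        self.z = np.ones(self.n_vco, dtype=complex)  # ideal-tier state
        self.tuning: VCOTuning | None = None
        self._xf = None  # neural-tier filtered state (nv, 3)
        self._y = None  # neural-tier filtered output (nv, 2)
        self._voltage = None
        self._refr = None
        if tier in ("rate", "spiking"):
            if tuning is not None:
                if tuning.enc_sc.shape[:2] != (self.n_vco, n_per_vco):
                    raise ValueError("provided tuning does not match this bank")
                self.tuning = tuning
                self.omega_scale = tuning.omega_scale
            else:
                self.tuning = _solve_vco_tuning(
                    self.n_vco,
                    n_per_vco,
                    self.omega_scale,
                    tau_syn,
                    self.lif,
                    seed,
                    dt=dt,
                    eval_style=eval_style,
                    reg=reg,
                )

    # -- state -------------------------------------------------------------
    @property
    def radii(self) -> np.ndarray:
        if self.tier == "ideal":
            return np.abs(self.z)
        return np.hypot(self._y[:, 0], self._y[:, 1]).astype(float)

    def half_spectrum(self) -> np.ndarray:
        if self.tier == "ideal":
            return self.z.copy()
        return (self._y[:, 0] + 1j * self._y[:, 1]).astype(complex)

    def set_position(self, x0) -> None:
        """Reset the oscillators to the spectrum of the encoded point."""
        x0 = np.asarray(x0, dtype=float)
        phases = self.enc.A_half @ x0
        z = np.exp(1j * phases)
        self.z = z
        if self.tier in ("rate", "spiking"):
            dtype = self.tuning.enc_sc.dtype
            nv = self.n_vco
            self._xf = np.zeros((nv, 3), dtype=dtype)
            self._xf[:, 1] = z.real
            self._xf[:, 2] = z.imag
            self._y = np.zeros((nv, 2), dtype=dtype)
            self._y[:, 0] = z.real
            self._y[:, 1] = z.imag
            self._voltage = np.zeros((nv, self.n_per_vco), dtype=dtype)
            self._refr = np.zeros((nv, self.n_per_vco), dtype=dtype)

    def save_state(self, path, readout=None) -> None:
        """Dump the current oscillator state (and decode, if a readout is
        given) to HDF5 for offline analysis."""
        import h5py

        half = self.half_spectrum()
        with h5py.File(path, "w") as fh:
            fh.attrs["tier"] = self.tier
            fh.attrs["d"] = self.enc.d
            fh.attrs["omega_scale"] = self.omega_scale
            fh.create_dataset("half_spectrum_re", data=half.real)
            fh.create_dataset("half_spectrum_im", data=half.imag)
            fh.create_dataset("assembled", data=self.assemble_ssp())
            if readout is not None:
                try:
                    fh.create_dataset(
                        "map_decode", data=readout.map_decode(self.assemble_ssp())
                    )
                except Exception:
                    pass

    def assemble_ssp(self) -> np.ndarray:
        """Mirror the half-spectrum (DC=1) into a real d-vector estimate."""
        F = np.empty(self.n_vco + 1, dtype=complex)
        F[0] = 1.0
        F[1:] = self.half_spectrum()
        return np.fft.irfft(F, n=self.enc.d)

    # -- stepping ----------------------------------------------------------
    def step(self, xdot=None, correction=None, dt: float = 1e-3, omega=None):
        """Advance one step given a velocity (or frequencies) and optional
        correction d-vector (applied as input current at the configured gain)."""
        if omega is None:
            xdot = np.zeros(self.enc.m) if xdot is None else xdot
            omega = velocity_to_frequencies(self.enc, xdot)
        self.run(np.asarray(omega, dtype=float)[None, :], correction, dt)
        return self

    def run(self, omega_seq: np.ndarray, correction=None, dt: float = 1e-3):
        """Advance len(omega_seq) steps; the correction is held constant."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        corr_half = np.zeros(self.n_vco, dtype=complex)
        if correction is not None:
            corr_half = np.fft.rfft(np.asarray(correction, dtype=float))[1:]
            corr_half = corr_half * self.correction_gain
        if self.tier == "ideal":
            z = self.z
            for k in range(omega_seq.shape[0]):
                w = omega_seq[k]
                z = _rk4_step(z, w, corr_half, dt)
            self.z = z
        else:
            tun = self.tuning
            dtype = tun.enc_sc.dtype
            w_norm = (omega_seq / self.omega_scale).astype(dtype)
            ucorr = (
                np.stack([corr_half.real, corr_half.imag], axis=1) * self.tau_syn
            ).astype(dtype)
            ksyn = dtype.type(1.0 - np.exp(-dt / self.tau_syn))
            if self.tier == "rate":
                _kernels.vco_chunk_rate(
                    self._xf,
                    self._y,
                    tun.enc_sc,
                    tun.bias,
                    tun.dec,
                    w_norm,
                    ucorr,
                    dtype.type(self.lif.tau_rc),
                    dtype.type(self.lif.tau_ref),
                    ksyn,
                )
            else:
                _kernels.vco_chunk_spiking(
                    self._xf,
                    self._y,
                    self._voltage,
                    self._refr,
                    tun.enc_sc,
                    tun.bias,
                    tun.dec,
                    w_norm,
                    ucorr,
                    dtype.type(dt),
                    dtype.type(self.lif.tau_rc),
                    dtype.type(self.lif.tau_ref),
                    ksyn,
                )
        return self


def _rk4_step(z, omega, corr_half, dt):
    def f(zz):
        return _stabilized_field(zz, omega) + corr_half

    k1 = f(z)
    k2 = f(z + 0.5 * dt * k1)
    k3 = f(z + 0.5 * dt * k2)
    k4 = f(z + dt * k3)
    return z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def pi_init(
    enc: SSPEncoder,
    x0,
    tier: str = "ideal",
    **kwargs,
) -> PathIntegrator:
    """Build a path integrator initialized at the encoded starting point."""
    pi = PathIntegrator(enc, tier=tier, **kwargs)
    pi.set_position(x0)
    return pi


def pi_step(pi: PathIntegrator, xdot, correction=None, dt: float = 1e-3):
    return pi.step(xdot=xdot, correction=correction, dt=dt)


def assemble_ssp(pi: PathIntegrator) -> np.ndarray:
    return pi.assemble_ssp()


@dataclass
class GridCellPopulation:
    """Neurons with point-encoding receptive fields over the cleaned estimate.

    With a hexagonal encoder, each neuron's encoder keeps only one
    wave-vector triplet (a single spatial-frequency module) of the point
    encoding, so its tuning over space is a sum of three plane waves at
    120 degrees — a hexagonal firing lattice.  For other encoder styles the
    full point encoding is used (place-like fields).
    """

    pop: Population
    enc: SSPEncoder
    modules: np.ndarray | None = None  # per-neuron module index (hexagonal)
    preferred: np.ndarray | None = None  # per-neuron anchor point

    @classmethod
    def build(
        cls,
        enc: SSPEncoder,
        n: int = 1000,
        lif: LIFParams | None = None,
        seed: int = 0,
    ) -> "GridCellPopulation":
        rng = np.random.default_rng(seed)
        lo, hi = enc.domain_bounds[:, 0], enc.domain_bounds[:, 1]
        anchors = rng.uniform(lo, hi, size=(n, enc.m))
        eval_points = enc.encode_vec(rng.uniform(lo, hi, size=(1000, enc.m)))
        modules = None
        if enc.style == "hexagonal":
            n_modules = enc.n_half // 3
            modules = rng.integers(0, n_modules, size=n)
            E = np.empty((n, enc.d))
            for i in range(n):
                sl = slice(3 * modules[i], 3 * modules[i] + 3)
                F = np.zeros(enc.n_half + 1, dtype=complex)
                F[1 + 3 * modules[i] : 4 + 3 * modules[i]] = np.exp(
                    1j * (enc.A_half[sl] @ anchors[i])
                )
                E[i] = np.fft.irfft(F, n=enc.d)
            pop = make_population(
                n,
                enc.d,
                encoder_style="provided",
                encoders=E,
                lif=lif or LIFParams(),
                seed=seed,
                eval_points=eval_points,
            )
        else:
            pop = make_population(
                n,
                enc.d,
                encoder_style="provided",
                encoders=enc.encode_vec(anchors),
                lif=lif or LIFParams(),
                seed=seed,
                eval_points=eval_points,
            )
        return cls(pop=pop, enc=enc, modules=modules, preferred=anchors)


def gc_update(
    gc: GridCellPopulation, pi_output: np.ndarray, readout: ProbabilityReadout
):
    """Clean the estimate (decode + re-encode) and fire the population on it.

    On decode failure the raw estimate passes through unchanged with the
    ``passthrough`` flag set.
    """
    try:
        clean = readout.cleanup(pi_output)
        vec = np.asarray(clean)
        passthrough = False
    except DecodeFailure:
        vec = np.asarray(pi_output, dtype=float)
        passthrough = True
    acts = gc.pop.rates(vec)
    return SSP(vec, gc.enc, clean=not passthrough), acts, passthrough
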